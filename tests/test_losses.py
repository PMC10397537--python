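import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragclr.losses import (
    LossConfig,
    SimilarityMatrix,
    nt_xent,
    similarity_loss,
    similarity_matrix,
    total_loss,
)


def _naive_nt_xent(p_mol, p_fv, tau, mode="as_printed"):
    """Double-loop reference implementation, written directly from the
    per-molecule definition."""
    n = len(p_mol)
    l_mol, l_fv = [], []
    for i in range(n):
        num = np.exp(p_mol[i] @ p_fv[i] / tau)
        den_m = den_f = 0.0
        for k in range(n):
            if k != i:
                den_m += np.exp(p_mol[i] @ p_mol[k] / tau)
                den_m += np.exp(p_mol[i] @ p_fv[k] / tau)
                den_f += np.exp(p_fv[i] @ p_mol[k] / tau)
                den_f += np.exp(p_fv[i] @ p_fv[k] / tau)
        if mode == "simclr":
            den_m += num
            den_f += np.exp(p_fv[i] @ p_mol[i] / tau)
        l_mol.append(-np.log(num / den_m))
        l_fv.append(-np.log(num / den_f))
    return np.array(l_mol), np.array(l_fv)


def _random_unit(rng, n, d):
    p = rng.normal(size=(n, d))
    return p / np.linalg.norm(p, axis=1, keepdims=True)


def test_orthogonal_projections_closed_form():
    """N=2, tau=1, four mutually orthogonal projections: every term is log 2."""
    e = np.eye(4)
    report = nt_xent(e[:2], e[2:], LossConfig(temperature=1.0))
    assert np.allclose(report.per_molecule_mol_terms, np.log(2), atol=1e-9)
    assert np.allclose(report.per_molecule_fv_terms, np.log(2), atol=1e-9)
    assert abs(report.L_clr - 4 * np.log(2)) < 1e-9


def test_aligned_within_molecule_closed_form():
    """Positive pairs identical, negatives orthogonal: each term log 2 - 1."""
    p = np.eye(4)[:2]
    report = nt_xent(p, p.copy(), LossConfig(temperature=1.0))
    assert np.allclose(report.per_molecule_mol_terms, np.log(2) - 1, atol=1e-9)
    assert abs(report.L_clr - 4 * (np.log(2) - 1)) < 1e-9


@pytest.mark.parametrize("n", [2, 4, 8])
def test_infinite_temperature_limit(n, rng):
    """tau -> inf flattens all similarities: L_clr -> 2N log(2(N-1))."""
    p_mol = _random_unit(rng, n, 6)
    p_fv = _random_unit(rng, n, 6)
    report = nt_xent(p_mol, p_fv, LossConfig(temperature=1e6))
    assert abs(report.L_clr - 2 * n * np.log(2 * (n - 1))) < 1e-4


@pytest.mark.parametrize("seed", range(20))
@pytest.mark.parametrize("mode", ["as_printed", "simclr"])
def test_matches_naive_double_loop(seed, mode):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    tau = float(rng.uniform(0.05, 2.0))
    p_mol = _random_unit(rng, n, 8)
    p_fv = _random_unit(rng, n, 8)
    report = nt_xent(p_mol, p_fv,
                     LossConfig(temperature=tau, denominator_mode=mode))
    l_mol, l_fv = _naive_nt_xent(p_mol, p_fv, tau, mode)
    assert np.abs(report.per_molecule_mol_terms - l_mol).max() < 1e-6
    assert np.abs(report.per_molecule_fv_terms - l_fv).max() < 1e-6
    assert abs(report.L_clr - (l_mol.sum() + l_fv.sum())) < 1e-6


def test_simclr_denominator_larger(rng):
    """Including the positive pair in the denominator raises every term."""
    p_mol = _random_unit(rng, 4, 8)
    p_fv = _random_unit(rng, 4, 8)
    as_printed = nt_xent(p_mol, p_fv, LossConfig(denominator_mode="as_printed"))
    simclr = nt_xent(p_mol, p_fv, LossConfig(denominator_mode="simclr"))
    assert np.all(simclr.per_molecule_mol_terms > as_printed.per_molecule_mol_terms)


def test_batch_permutation_invariance(rng):
    p_mol = _random_unit(rng, 6, 8)
    p_fv = _random_unit(rng, 6, 8)
    cfg = LossConfig()
    perm = rng.permutation(6)
    a = nt_xent(p_mol, p_fv, cfg)
    b = nt_xent(p_mol[perm], p_fv[perm], cfg)
    assert abs(a.L_clr - b.L_clr) < 1e-9


def test_positive_similarity_monotonicity():
    """Raising the positive-pair similarity (negatives fixed) lowers L_mol_i."""
    d = 4
    p_mol = np.eye(d)[:2]
    prev = np.inf
    for theta in np.linspace(np.pi / 2, 0.0, 8):
        p_fv = np.stack([
            np.cos(theta) * np.eye(d)[0] + np.sin(theta) * np.eye(d)[2],
            np.eye(d)[3],
        ])
        term = nt_xent(p_mol, p_fv, LossConfig(temperature=0.5)) \
            .per_molecule_mol_terms[0]
        assert term < prev
        prev = term


def test_nt_xent_errors(rng):
    cfg = LossConfig()
    with pytest.raises(ValueError):
        nt_xent(np.eye(3)[:1], np.eye(3)[1:2], cfg)
    with pytest.raises(ValueError):
        nt_xent(2 * np.eye(2), np.eye(2), cfg)


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(temperature=0.0)
    with pytest.raises(ValueError):
        LossConfig(gamma=-0.1)
    with pytest.raises(ValueError):
        LossConfig(denominator_mode="bogus")


# ---- similarity matrix and auxiliary loss -----------------------------------


def test_similarity_matrix_trivials():
    ones = similarity_matrix(np.tile([1.0, 0.0], (3, 1)))
    assert np.allclose(ones.values, 1.0)
    ident = similarity_matrix(np.eye(3))
    assert np.allclose(ident.values, np.eye(3))
    single = similarity_matrix(np.array([[0.6, 0.8]]))
    assert np.allclose(single.values, [[1.0]])


@settings(derandomize=True, max_examples=30)
@given(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=999))
def test_similarity_matrix_invariants(nb, seed):
    rng = np.random.default_rng(seed)
    mat = similarity_matrix(_random_unit(rng, nb, 5)).values
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 1.0, atol=1e-6)
    assert np.all(mat >= -1 - 1e-9) and np.all(mat <= 1 + 1e-9)


@pytest.mark.parametrize(
    "values, expected",
    [
        (np.ones((3, 3)), 0.0),
        (np.eye(2), 0.5),
        (np.array([[1.0, -1.0], [-1.0, 1.0]]), 2.0),
    ],
)
def test_similarity_loss_closed_forms(values, expected):
    terms, total = similarity_loss([SimilarityMatrix(values)])
    assert abs(total - expected) < 1e-9
    assert abs(terms[0] - expected) < 1e-9


def test_similarity_loss_sums_over_molecules():
    mats = [SimilarityMatrix(np.eye(2)), SimilarityMatrix(np.ones((2, 2)))]
    terms, total = similarity_loss(mats)
    assert np.allclose(terms, [0.5, 0.0])
    assert abs(total - 0.5) < 1e-12


def test_similarity_loss_zero_iff_identical(rng):
    """L_sim_k vanishes exactly when all fragment projections coincide —
    the collapse fixed point."""
    p = _random_unit(rng, 1, 5)
    identical = np.tile(p, (4, 1))
    _, zero = similarity_loss([similarity_matrix(identical)])
    assert zero < 1e-12
    distinct = _random_unit(rng, 4, 5)
    _, positive = similarity_loss([similarity_matrix(distinct)])
    assert positive > 1e-6


def test_similarity_loss_errors():
    with pytest.raises(ValueError):
        similarity_loss([])
    with pytest.raises(ValueError):
        SimilarityMatrix(np.zeros((0, 0)))


@pytest.mark.parametrize(
    "gamma, l_sim, l_clr, expected",
    [(0.0, 5.0, 1.3, 1.3), (0.01, 2.0, 1.0, 1.02), (0.1, 0.0, 0.7, 0.7)],
)
def test_total_loss(gamma, l_sim, l_clr, expected):
    cfg = LossConfig(gamma=gamma)
    assert abs(total_loss(l_clr, l_sim, cfg) - expected) < 1e-12
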