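"""Contrastive (NT-Xent) and auxiliary fragment-similarity losses.

For a batch of N molecules the two branches give unit-norm projections
``p_mol_i`` and ``p_fv_i``.  The per-molecule contrastive terms are

    L_mol_i = -log[ exp(<p_mol_i, p_fv_i>/tau)
                    / sum_{k != i} ( exp(<p_mol_i, p_mol_k>/tau)
                                   + exp(<p_mol_i, p_fv_k>/tau) ) ],

with the symmetric ``L_fv_i`` anchored on ``p_fv_i``, and
``L_clr = sum_i (L_mol_i + L_fv_i)``.  The indicator ``k != i`` excludes the
positive pair from the denominator (``as_printed`` mode); a ``simclr`` mode
that keeps the positive in the denominator, as SimCLR does, is available as a
config flag.  The direction of optimisation is the standard negative-log form:
raising the positive-pair similarity lowers the loss.

Each molecule k with Nb_k fragment-pair views also yields a similarity matrix
``S_k`` of inner products between its per-view projections; the auxiliary loss

    L_sim_k = (1/Nb_k^2) * sum_ij (s_ij - 1)^2

pulls the per-view projections of a molecule together (an over-weighted
auxiliary loss collapses them to a single point).  The total pre-training loss
is ``L = gamma * L_sim + L_clr``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack_rows

__all__ = [
    "LossConfig",
    "LossReport",
    "SimilarityMatrix",
    "nt_xent",
    "nt_xent_t",
    "similarity_matrix",
    "similarity_loss",
    "similarity_loss_t",
    "total_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Temperature, auxiliary-loss weight and denominator convention.

    ``temperature`` rescales the inner-product similarities; ``gamma`` weighs
    the auxiliary similarity loss in the total (``gamma = 0`` disables it).
    """

    temperature: float = 0.1
    gamma: float = 0.01
    denominator_mode: str = "as_printed"  # or "simclr"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.denominator_mode not in ("as_printed", "simclr"):
            raise ValueError(f"unknown denominator_mode {self.denominator_mode!r}")


@dataclass
class SimilarityMatrix:
    """Inner products between the unit-norm per-view projections of one molecule."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] == 0:
            raise ValueError("similarity matrix must be square and non-empty")
        self.values = v


@dataclass
class LossReport:
    """Per-molecule and aggregate loss terms for one batch."""

    per_molecule_mol_terms: np.ndarray
    per_molecule_fv_terms: np.ndarray
    L_clr: float
    per_molecule_sim_terms: np.ndarray | None = None
    L_sim: float | None = None
    total: float | None = None


def _check_unit(p: np.ndarray, name: str, atol: float = 1e-6) -> None:
    norms = np.linalg.norm(p, axis=-1)
    if not np.allclose(norms, 1.0, atol=atol):
        raise ValueError(f"{name} must be unit-norm (got norms {norms})")


def nt_xent_t(p_mol: Tensor, p_fv: Tensor, cfg: LossConfig) -> tuple[Tensor, Tensor, Tensor]:
    """Differentiable NT-Xent; returns (per-mol terms, per-fv terms, L_clr)."""
    n = p_mol.shape[0]
    if n < 2:
        raise ValueError("NT-Xent needs a batch of at least 2 molecules")
    tau = cfg.temperature
    mm = (p_mol @ p_mol.T) * (1.0 / tau)
    ff = (p_fv @ p_fv.T) * (1.0 / tau)
    mf = (p_mol @ p_fv.T) * (1.0 / tau)
    off = 1.0 - np.eye(n)
    pos = mf * Tensor.const(np.eye(n))  # diagonal holds the positive pairs
    pos_row = pos.sum(axis=1)

    def _branch(anchor_cross: Tensor, anchor_same: Tensor) -> Tensor:
        # anchor_same: similarities to same-branch others; anchor_cross: to the
        # other branch.  In simclr mode the positive re-enters the denominator.
        ex_same = anchor_same.exp() * Tensor.const(off)
        if cfg.denominator_mode == "as_printed":
            ex_cross = anchor_cross.exp() * Tensor.const(off)
        else:
            ex_cross = anchor_cross.exp()
        denom = (ex_same + ex_cross).sum(axis=1)
        return -(pos_row - denom.log())

    l_mol = _branch(mf, mm)
    l_fv = _branch(mf.T, ff)
    return l_mol, l_fv, l_mol.sum() + l_fv.sum()


def nt_xent(p_mol: np.ndarray, p_fv: np.ndarray, cfg: LossConfig) -> LossReport:
    """NT-Xent over a batch of unit-norm projection pairs."""
    p_mol = np.asarray(p_mol, dtype=np.float64)
    p_fv = np.asarray(p_fv, dtype=np.float64)
    _check_unit(p_mol, "p_mol")
    _check_unit(p_fv, "p_fv")
    l_mol, l_fv, l_clr = nt_xent_t(Tensor.const(p_mol), Tensor.const(p_fv), cfg)
    return LossReport(
        per_molecule_mol_terms=l_mol.data.copy(),
        per_molecule_fv_terms=l_fv.data.copy(),
        L_clr=float(l_clr.data),
    )


def similarity_matrix(p_frag: np.ndarray) -> SimilarityMatrix:
    """Pairwise inner products of one molecule's per-view projections."""
    p = np.asarray(p_frag, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] < 1:
        raise ValueError("p_frag must be a non-empty (Nb, d) array")
    _check_unit(p, "p_frag")
    return SimilarityMatrix(values=p @ p.T)


def similarity_loss_t(p_frag_list: list[list[Tensor]]) -> tuple[Tensor, Tensor]:
    """Differentiable auxiliary loss from per-molecule projection lists."""
    terms = []
    for vecs in p_frag_list:
        if len(vecs) == 0:
            raise ValueError("molecule with zero fragment views")
        P = stack_rows(vecs)
        S = P @ P.T
        terms.append(((S - 1.0) ** 2).mean())
    per_mol = stack_rows(terms)
    return per_mol, per_mol.sum()


def similarity_loss(mats: list[SimilarityMatrix]) -> tuple[np.ndarray, float]:
    """Mean squared deviation of each similarity matrix from all-ones, summed.

    Each per-molecule term lies in [0, 4] and vanishes exactly when all of the
    molecule's fragment projections coincide.
    """
    if not mats:
        raise ValueError("no similarity matrices given")
    terms = np.array([float(np.mean((m.values - 1.0) ** 2)) for m in mats])
    return terms, float(terms.sum())


def total_loss(L_clr: float, L_sim: float, cfg: LossConfig) -> float:
    """Total pre-training loss ``gamma * L_sim + L_clr``."""
    return cfg.gamma * L_sim + L_clr
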