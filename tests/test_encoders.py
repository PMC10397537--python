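import numpy as np
import pytest

import fragclr as fc
from fragclr.autodiff import Tensor
from fragclr.chem_io import BOND_FEATURE_DIM
from fragclr.encoders import (
    EncoderConfig,
    ProjectionHead,
    TwoBranchModel,
    _GraphArrays,
    load_checkpoint,
    save_checkpoint,
)


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(embedding_dim=30, fusion_heads=4)
    with pytest.raises(ValueError):
        EncoderConfig(message_passing_steps=0)


def test_encode_molecule_deterministic(small_model):
    g = fc.parse_smiles("CC(=O)c1ccccc1")
    h1 = fc.encode_molecule(g, small_model)
    h2 = fc.encode_molecule(g, small_model)
    assert np.array_equal(h1, h2)


def test_same_seed_same_model(small_cfg):
    m1, m2 = TwoBranchModel(small_cfg), TwoBranchModel(small_cfg)
    assert m1.param_hash() == m2.param_hash()


def test_atom_relabeling_invariance(small_model):
    """Isomorphic graphs written with different atom orders embed identically."""
    pairs = [("CCO", "OCC"), ("CC(=O)c1ccccc1", "c1ccccc1C(C)=O"),
             ("CC(C)C", "C(C)(C)C")]
    for a, b in pairs:
        ha = fc.encode_molecule(fc.parse_smiles(a), small_model)
        hb = fc.encode_molecule(fc.parse_smiles(b), small_model)
        assert np.abs(ha - hb).max() < 1e-8


def test_distinct_molecules_distinct_embeddings(small_model, toy_graphs):
    hs = [fc.encode_molecule(g, small_model) for g in toy_graphs]
    for i in range(len(hs)):
        for j in range(i + 1, len(hs)):
            assert np.abs(hs[i] - hs[j]).max() > 1e-8


def test_empty_graph_rejected(small_model):
    g = fc.parse_smiles("C")
    g2 = fc.parse_smiles("CC")
    empty = fc.chem_io.MolecularGraph(atoms=[], edges=frozenset(),
                                      edge_features={}, smiles="", mol=g.mol)
    with pytest.raises(ValueError):
        small_model.encode_molecule_t(empty)
    # single atoms and normal molecules are fine
    assert fc.encode_molecule(g, small_model).shape == (16,)
    assert fc.encode_molecule(g2, small_model).shape == (16,)


def test_fragment_pair_component_swap(small_model):
    """Relabeling the two components leaves the embedding unchanged."""
    g = fc.parse_smiles("CCOC")
    v = fc.all_views(g)[0]
    h1 = fc.encode_fragment_pair(v, small_model)
    swapped = fc.views.FragmentPairView(
        parent=v.parent, removed_edge=v.removed_edge, edges_prime=v.edges_prime,
        component_assignment={k: 1 - c for k, c in v.component_assignment.items()},
    )
    h2 = fc.encode_fragment_pair(swapped, small_model)
    assert np.abs(h1 - h2).max() < 1e-12


def _encode_component_alone(model, view, comp):
    """Encode one component of a view as if it were a standalone graph,
    keeping the original atom annotations (including heavy_degree)."""
    g = view.parent
    atoms = sorted(i for i, c in view.component_assignment.items() if c == comp)
    remap = {a: k for k, a in enumerate(atoms)}
    arrays = _GraphArrays.__new__(_GraphArrays)
    arrays.n = len(atoms)
    arrays.n_components = 1
    arrays.X = Tensor.const(g.atom_matrix()[atoms])
    src, dst, bf = [], [], []
    for e in sorted(view.edges_prime):
        if e[0] in remap and e[1] in remap:
            i, j = remap[e[0]], remap[e[1]]
            vbf = g.bond_vector(e)
            src += [i, j]
            dst += [j, i]
            bf += [vbf, vbf]
    arrays.src = np.asarray(src, dtype=np.intp)
    arrays.dst = np.asarray(dst, dtype=np.intp)
    arrays.B = Tensor.const(np.asarray(bf).reshape(len(src), BOND_FEATURE_DIM))
    arrays.comp = np.zeros(len(atoms), dtype=np.intp)
    return model._encode(arrays, "frag").data[0]


def test_separate_readout_equals_per_component_encoding(small_model):
    """No message crosses the broken bond: encoding the disconnected view
    equals encoding each component alone and summing the readouts."""
    for smiles in ("CCC", "CC(=O)c1ccccc1", "CCOC(C)=O"):
        g = fc.parse_smiles(smiles)
        for v in fc.all_views(g):
            whole = fc.encode_fragment_pair(v, small_model)
            parts = sum(
                _encode_component_alone(small_model, v, c) for c in (0, 1)
            )
            assert np.abs(whole - parts).max() < 1e-9


def test_isomorphic_components_double_single_readout(small_model):
    """Ethane's view has two identical single-carbon components, so the pair
    embedding is twice either component's readout."""
    g = fc.parse_smiles("CC")
    (v,) = fc.all_views(g)
    whole = fc.encode_fragment_pair(v, small_model)
    part = _encode_component_alone(small_model, v, 0)
    assert np.abs(whole - 2 * part).max() < 1e-9


def test_fragment_pair_requires_two_components(small_model):
    g = fc.parse_smiles("CCO")
    v = fc.all_views(g)[0]
    bad = fc.views.FragmentPairView(
        parent=v.parent, removed_edge=v.removed_edge, edges_prime=v.edges_prime,
        component_assignment={k: 0 for k in v.component_assignment},
    )
    with pytest.raises(ValueError):
        small_model.encode_fragment_pair_t(bad)


def test_fusion_single_token_identity(small_model, rng):
    h = [rng.normal(size=16)]
    fused, h_fv = fc.fuse_views(h, small_model)
    assert np.array_equal(fused[0], h_fv)


def test_fusion_permutation_invariance(small_model, toy_graphs, rng):
    """h_fv is unchanged (max abs < 1e-5) under 10 random permutations of the
    fragment-view token order, for every toy molecule with views."""
    for g in toy_graphs:
        views = fc.all_views(g)
        if not views:
            continue
        h_frag = [fc.encode_fragment_pair(v, small_model) for v in views]
        _, ref = fc.fuse_views(h_frag, small_model)
        for _ in range(10):
            perm = rng.permutation(len(h_frag))
            _, out = fc.fuse_views([h_frag[i] for i in perm], small_model)
            assert np.abs(out - ref).max() < 1e-5


def test_fusion_sum_consistency(small_model, rng):
    """h_fv equals an independently recomputed sum of the fused tokens."""
    h = [rng.normal(size=16) for _ in range(3)]
    fused, h_fv = fc.fuse_views(h, small_model)
    assert np.abs(np.sum(np.stack(fused), axis=0) - h_fv).max() < 1e-12


def test_fusion_empty_rejected(small_model):
    with pytest.raises(ValueError):
        small_model.fuse_views_t([])


def test_projection_unit_norm(small_model, rng):
    for name in ("mol", "fv", "frag"):
        p = fc.project(rng.normal(size=16), small_model.heads[name])
        assert abs(np.linalg.norm(p) - 1.0) < 1e-6


def test_projection_deterministic(small_model, rng):
    h = rng.normal(size=16)
    assert np.array_equal(fc.project(h, small_model.heads["mol"]),
                          fc.project(h, small_model.heads["mol"]))


def test_linear_head_scale_invariance(rng):
    head = ProjectionHead(8, 8, 8, np.random.default_rng(1),
                          activation="identity", bias=False)
    h = rng.normal(size=8)
    p1 = fc.project(h, head)
    p2 = fc.project(2 * h, head)
    assert np.abs(p1 - p2).max() < 1e-10


def test_degenerate_projection_rejected():
    head = ProjectionHead(8, 8, 8, np.random.default_rng(1),
                          activation="identity", bias=False)
    with pytest.raises(ValueError):
        fc.project(np.zeros(8), head)


def test_embedding_set_sum_invariant(small_model):
    g = fc.parse_smiles("CC(=O)c1ccccc1")
    es = small_model.embed(g, fc.all_views(g))
    assert len(es.h_frag) == len(es.h_frag_fused) == 2
    assert np.abs(np.sum(np.stack(es.h_frag_fused), axis=0) - es.h_fv).max() < 1e-12


def test_checkpoint_roundtrip(small_model, tmp_path):
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, small_model)
    loaded = load_checkpoint(path)
    assert loaded.param_hash() == small_model.param_hash()
    assert loaded.cfg == small_model.cfg


def test_checkpoint_scheme_mismatch_refused(small_model, tmp_path, monkeypatch):
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, small_model)
    monkeypatch.setattr(fc.encoders, "FEATURE_SCHEME_VERSION", "other-scheme")
    with pytest.raises(ValueError, match="feature scheme"):
        load_checkpoint(path)
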