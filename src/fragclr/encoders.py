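"""Two-branch encoder: molecule view, fragment-pair views, Transformer fusion.

The molecule-view branch embeds the intact graph with an attention-readout
message-passing encoder (gated recurrent atom updates with neighbour
attention, followed by a recurrent super-node readout, in the style of
attentive-fingerprint networks).  The fragment-view branch runs a second
encoder with its own weights on each fragment-pair view: message passing never
crosses the broken bond, the two components are read out separately and the
two component embeddings are summed element-wise.  A Transformer encoder
without positional encodings then fuses the per-view embeddings as an
unordered token set; the fragment-view representation ``h_fv`` is the
element-wise sum of the fused tokens.  Three independent projection heads map
``h_mol``, ``h_fv`` and each per-view ``h_frag_i`` onto the unit sphere where
the contrastive and similarity losses live.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, stack_rows
from .chem_io import (
    ATOM_FEATURE_DIM,
    BOND_FEATURE_DIM,
    FEATURE_SCHEME_VERSION,
    MolecularGraph,
)
from .views import FragmentPairView

__all__ = [
    "EncoderConfig",
    "EmbeddingSet",
    "TwoBranchModel",
    "encode_molecule",
    "encode_fragment_pair",
    "fuse_views",
    "project",
    "ProjectionHead",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters shared by both branches.

    Defaults are sized for a workstation; the model family itself has no
    intrinsic scale.
    """

    embedding_dim: int = 256
    message_passing_steps: int = 2
    readout_steps: int = 2
    fusion_layers: int = 2
    fusion_heads: int = 4
    projection_hidden_dim: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim % self.fusion_heads != 0:
            raise ValueError("embedding_dim must be divisible by fusion_heads")
        for name in ("embedding_dim", "message_passing_steps", "readout_steps",
                     "fusion_layers", "fusion_heads", "projection_hidden_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EmbeddingSet:
    """All embeddings the model produces for one molecule."""

    h_mol: np.ndarray
    h_frag: list[np.ndarray]
    h_frag_fused: list[np.ndarray]
    h_fv: np.ndarray


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


def _linear(params: dict, prefix: str, rng, n_in: int, n_out: int) -> None:
    params[prefix + ".W"] = Tensor.param(_glorot(rng, n_in, n_out))
    params[prefix + ".b"] = Tensor.param(np.zeros(n_out))


def _apply_linear(params: dict, prefix: str, x: Tensor) -> Tensor:
    return x @ params[prefix + ".W"] + params[prefix + ".b"]


def _gru_params(params: dict, prefix: str, rng, d: int) -> None:
    for gate in ("z", "r", "n"):
        params[f"{prefix}.W{gate}"] = Tensor.param(_glorot(rng, d, d))
        params[f"{prefix}.U{gate}"] = Tensor.param(_glorot(rng, d, d))
        params[f"{prefix}.b{gate}"] = Tensor.param(np.zeros(d))


def _gru(params: dict, prefix: str, x: Tensor, h: Tensor) -> Tensor:
    z = (x @ params[f"{prefix}.Wz"] + h @ params[f"{prefix}.Uz"]
         + params[f"{prefix}.bz"]).sigmoid()
    r = (x @ params[f"{prefix}.Wr"] + h @ params[f"{prefix}.Ur"]
         + params[f"{prefix}.br"]).sigmoid()
    n = (x @ params[f"{prefix}.Wn"] + (r * h) @ params[f"{prefix}.Un"]
         + params[f"{prefix}.bn"]).tanh()
    return (1.0 - z) * h + z * n


def _segment_softmax(scores: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Softmax of a score column grouped by segment id (numerically shifted)."""
    shift = np.full(n_seg, -np.inf)
    np.maximum.at(shift, seg, scores.data[:, 0])
    shift[~np.isfinite(shift)] = 0.0
    ex = (scores - Tensor.const(shift[seg][:, None])).exp()
    denom = ex.segment_sum(seg, n_seg)
    return ex / denom.gather(seg)


def _layer_norm(params: dict, prefix: str, x: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps) ** 0.5 * params[prefix + ".g"] + params[prefix + ".b"]


def _cols(x: Tensor, lo: int, hi: int) -> Tensor:
    return x.T.gather(np.arange(lo, hi)).T


class _GraphArrays:
    """Flat array form of one (possibly disconnected) annotated graph."""

    def __init__(self, g: MolecularGraph, edges: frozenset, comp_of: dict[int, int],
                 n_components: int):
        self.n = g.n_atoms
        self.n_components = n_components
        self.X = Tensor.const(g.atom_matrix())
        src, dst, bf = [], [], []
        for e in sorted(edges):
            i, j = e
            v = g.bond_vector(e)
            src += [i, j]
            dst += [j, i]
            bf += [v, v]
        self.src = np.asarray(src, dtype=np.intp)
        self.dst = np.asarray(dst, dtype=np.intp)
        self.B = Tensor.const(np.asarray(bf).reshape(len(src), BOND_FEATURE_DIM))
        self.comp = np.asarray([comp_of[i] for i in range(self.n)], dtype=np.intp)


class TwoBranchModel:
    """Holds every learnable parameter of the two branches plus fusion/heads."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(cfg.seed)
        d = cfg.embedding_dim
        for enc in ("mol", "frag"):
            _linear(self.params, f"{enc}.embed", rng, ATOM_FEATURE_DIM, d)
            _linear(self.params, f"{enc}.msg", rng, d + BOND_FEATURE_DIM, d)
            _linear(self.params, f"{enc}.att", rng, 2 * d + BOND_FEATURE_DIM, 1)
            _gru_params(self.params, f"{enc}.node_gru", rng, d)
            _linear(self.params, f"{enc}.read_att", rng, 2 * d, 1)
            _linear(self.params, f"{enc}.read_msg", rng, d, d)
            _gru_params(self.params, f"{enc}.read_gru", rng, d)
        for layer in range(cfg.fusion_layers):
            p = f"fusion.{layer}"
            for mat in ("Wq", "Wk", "Wv", "Wo"):
                self.params[f"{p}.{mat}"] = Tensor.param(_glorot(rng, d, d))
            _linear(self.params, f"{p}.ff1", rng, d, 2 * d)
            _linear(self.params, f"{p}.ff2", rng, 2 * d, d)
            for ln in ("ln1", "ln2"):
                self.params[f"{p}.{ln}.g"] = Tensor.param(np.ones(d))
                self.params[f"{p}.{ln}.b"] = Tensor.param(np.zeros(d))
        self.heads = {
            name: ProjectionHead(d, cfg.projection_hidden_dim, d, rng,
                                 params=self.params, prefix=f"head.{name}")
            for name in ("mol", "fv", "frag")
        }

    # ---- graph encoding -----------------------------------------------------

    def _encode(self, arrays: _GraphArrays, enc: str) -> Tensor:
        """Run message passing + per-component attention readout.

        Returns an ``(n_components, d)`` tensor of component embeddings.
        Messages flow only along edges, so components never exchange
        information; the readout pools atoms within each component.
        """
        P, cfg = self.params, self.cfg
        H = _apply_linear(P, f"{enc}.embed", arrays.X).relu()
        # atoms without incident edges receive a zero message but still pass
        # through the recurrent update, so a component embeds identically
        # whether it appears alone or inside a disconnected view
        for _ in range(cfg.message_passing_steps):
            hu = H.gather(arrays.src)
            hv = H.gather(arrays.dst)
            he = concat([hu, arrays.B], axis=-1)
            msg = _apply_linear(P, f"{enc}.msg", he).elu()
            scores = _apply_linear(
                P, f"{enc}.att", concat([hv, hu, arrays.B], axis=-1)
            ).leaky_relu()
            attn = _segment_softmax(scores, arrays.dst, arrays.n)
            m = (attn * msg).segment_sum(arrays.dst, arrays.n)
            H = _gru(P, f"{enc}.node_gru", m, H)
        G = H.segment_sum(arrays.comp, arrays.n_components)
        for _ in range(cfg.readout_steps):
            g_per_atom = G.gather(arrays.comp)
            scores = _apply_linear(
                P, f"{enc}.read_att", concat([g_per_atom, H], axis=-1)
            ).leaky_relu()
            attn = _segment_softmax(scores, arrays.comp, arrays.n_components)
            ctx = (attn * _apply_linear(P, f"{enc}.read_msg", H).elu()).segment_sum(
                arrays.comp, arrays.n_components
            )
            G = _gru(P, f"{enc}.read_gru", ctx, G)
        return G

    def encode_molecule_t(self, g: MolecularGraph) -> Tensor:
        if g.n_atoms == 0:
            raise ValueError("cannot encode an empty graph")
        arrays = _GraphArrays(g, g.edges, {i: 0 for i in range(g.n_atoms)}, 1)
        return self._encode(arrays, "mol").reshape(self.cfg.embedding_dim)

    def encode_fragment_pair_t(self, v: FragmentPairView) -> Tensor:
        n_comp = len(set(v.component_assignment.values()))
        if n_comp != 2:
            raise ValueError(f"fragment-pair view must have 2 components, got {n_comp}")
        arrays = _GraphArrays(v.parent, v.edges_prime, v.component_assignment, 2)
        G = self._encode(arrays, "frag")
        return G.sum(axis=0)  # element-wise sum of the two component readouts

    # ---- fusion -------------------------------------------------------------

    def fuse_views_t(self, h_frag: list[Tensor]) -> tuple[list[Tensor], Tensor]:
        """Self-attention fusion of the per-view embeddings (no positions).

        Returns the fused tokens and their element-wise sum ``h_fv``.  Token
        order is immaterial: attention over an unordered set is
        permutation-equivariant and the final sum is permutation-invariant.
        """
        if len(h_frag) == 0:
            raise ValueError("fuse_views requires at least one fragment view")
        P, cfg = self.params, self.cfg
        d = cfg.embedding_dim
        dh = d // cfg.fusion_heads
        X = stack_rows(h_frag)
        for layer in range(cfg.fusion_layers):
            p = f"fusion.{layer}"
            Q, K, V = (X @ P[f"{p}.{m}"] for m in ("Wq", "Wk", "Wv"))
            head_outs = []
            for h in range(cfg.fusion_heads):
                lo, hi = h * dh, (h + 1) * dh
                Qh, Kh, Vh = _cols(Q, lo, hi), _cols(K, lo, hi), _cols(V, lo, hi)
                S = Qh @ Kh.T * (1.0 / np.sqrt(dh))
                shift = S.data.max(axis=-1, keepdims=True)
                E = (S - Tensor.const(shift)).exp()
                A = E / E.sum(axis=-1, keepdims=True)
                head_outs.append(A @ Vh)
            attn_out = concat(head_outs, axis=-1) @ P[f"{p}.Wo"]
            X = _layer_norm(P, f"{p}.ln1", X + attn_out)
            ff = _apply_linear(P, f"{p}.ff2",
                               _apply_linear(P, f"{p}.ff1", X).relu())
            X = _layer_norm(P, f"{p}.ln2", X + ff)
        fused = [X.gather(np.array([i])).reshape(d) for i in range(len(h_frag))]
        return fused, X.sum(axis=0)

    # ---- full per-molecule pass --------------------------------------------

    def embed_t(self, g: MolecularGraph, views: list[FragmentPairView]):
        h_mol = self.encode_molecule_t(g)
        h_frag = [self.encode_fragment_pair_t(v) for v in views]
        fused, h_fv = self.fuse_views_t(h_frag)
        return h_mol, h_frag, fused, h_fv

    def embed(self, g: MolecularGraph, views: list[FragmentPairView]) -> EmbeddingSet:
        h_mol, h_frag, fused, h_fv = self.embed_t(g, views)
        return EmbeddingSet(
            h_mol=h_mol.data,
            h_frag=[t.data for t in h_frag],
            h_frag_fused=[t.data for t in fused],
            h_fv=h_fv.data,
        )

    # ---- bookkeeping --------------------------------------------------------

    def param_hash(self) -> str:
        md = hashlib.sha256()
        for k in sorted(self.params):
            md.update(k.encode())
            md.update(np.ascontiguousarray(self.params[k].data).tobytes())
        return md.hexdigest()

    def encoder_param_names(self) -> list[str]:
        return [k for k in self.params
                if k.split(".")[0] in ("mol", "frag", "fusion", "head")]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=np.float64)


class ProjectionHead:
    """Two-layer feed-forward map followed by projection to the unit sphere."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator, activation: str = "relu",
                 bias: bool = True, params: dict | None = None,
                 prefix: str = "head"):
        self.activation = activation
        self.bias = bias
        store = params if params is not None else {}
        self.prefix = prefix
        store[f"{prefix}.W1"] = Tensor.param(_glorot(rng, d_in, d_hidden))
        store[f"{prefix}.W2"] = Tensor.param(_glorot(rng, d_hidden, d_out))
        if bias:
            store[f"{prefix}.b1"] = Tensor.param(np.zeros(d_hidden))
            store[f"{prefix}.b2"] = Tensor.param(np.zeros(d_out))
        self.store = store

    def __call__(self, h: Tensor) -> Tensor:
        z = h @ self.store[f"{self.prefix}.W1"]
        if self.bias:
            z = z + self.store[f"{self.prefix}.b1"]
        if self.activation == "relu":
            z = z.relu()
        elif self.activation != "identity":
            raise ValueError(f"unknown activation {self.activation!r}")
        p = z @ self.store[f"{self.prefix}.W2"]
        if self.bias:
            p = p + self.store[f"{self.prefix}.b2"]
        n = p.norm()
        if n.data < 1e-12:
            raise ValueError("degenerate projection: zero vector after head")
        return p / n


# ---- functional wrappers matching the operation-level API --------------------


def encode_molecule(g: MolecularGraph, model: TwoBranchModel) -> np.ndarray:
    """Embedding of the intact molecule view, ``h_mol``."""
    return model.encode_molecule_t(g).data


def encode_fragment_pair(v: FragmentPairView, model: TwoBranchModel) -> np.ndarray:
    """Embedding of one fragment-pair view (sum of the two component readouts)."""
    return model.encode_fragment_pair_t(v).data


def fuse_views(h_frag: list[np.ndarray], model: TwoBranchModel):
    """Fuse per-view embeddings; returns (fused token list, h_fv)."""
    fused, h_fv = model.fuse_views_t([Tensor.const(h) for h in h_frag])
    return [t.data for t in fused], h_fv.data


def project(h: np.ndarray, head: ProjectionHead) -> np.ndarray:
    """Unit-norm projection of an embedding."""
    return head(Tensor.const(h)).data


# ---- checkpoints -------------------------------------------------------------


def save_checkpoint(path: str | Path, model: TwoBranchModel) -> None:
    """Persist parameters, config and feature-scheme version to an ``.npz``."""
    meta = json.dumps(
        {"config": asdict(model.cfg), "feature_scheme": FEATURE_SCHEME_VERSION}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | Path) -> TwoBranchModel:
    """Load a checkpoint, refusing on a feature-scheme mismatch."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["feature_scheme"] != FEATURE_SCHEME_VERSION:
            raise ValueError(
                f"checkpoint feature scheme {meta['feature_scheme']!r} does not "
                f"match this build ({FEATURE_SCHEME_VERSION!r})"
            )
        model = TwoBranchModel(EncoderConfig(**meta["config"]))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
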