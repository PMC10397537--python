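"""Self-supervised pre-training of the two-branch contrastive model.

Each step embeds a batch of molecules through both branches, projects the
embeddings to the unit sphere, and minimises
``L = gamma * L_sim + L_clr`` with Adam.  A held-out fraction of the corpus
(5% by default) is used for model selection: the checkpoint returned is the
one with the lowest validation total loss over all epochs.  Molecules without
any breakable acyclic single bond carry no fragment view and are filtered out
of the corpus at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, stack_rows
from .chem_io import MolecularGraph
from .encoders import EncoderConfig, TwoBranchModel
from .losses import LossConfig, nt_xent_t, similarity_loss_t
from .views import FragmentPairView, all_views

logger = logging.getLogger(__name__)

__all__ = ["PretrainConfig", "PretrainResult", "split_pretrain", "pretrain",
           "filter_corpus", "batch_projections"]


@dataclass(frozen=True)
class PretrainConfig:
    """Pre-training hyperparameters (optimiser, batching, loss weights)."""

    batch_size: int = 16
    epochs: int = 20
    learning_rate: float = 1e-3
    validation_fraction: float = 0.05
    seed: int = 0
    gamma: float = 0.01
    temperature: float = 0.1
    denominator_mode: str = "as_printed"
    nb_cap: int | None = None
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2 (negatives needed)")

    def loss_config(self) -> LossConfig:
        return LossConfig(temperature=self.temperature, gamma=self.gamma,
                          denominator_mode=self.denominator_mode)


@dataclass
class PretrainResult:
    """Best model plus the full training trace."""

    model: TwoBranchModel
    best_epoch: int
    best_validation_loss: float
    train_losses: list[dict]     # per epoch: L_clr, L_sim, total
    validation_losses: list[float]
    initial_train_loss: float


def filter_corpus(
    corpus: list[MolecularGraph],
) -> tuple[list[tuple[MolecularGraph, list[FragmentPairView]]], int]:
    """Pair each molecule with its fragment-pair views; drop Nb = 0 molecules."""
    kept, dropped = [], 0
    for g in corpus:
        views = all_views(g)
        if views:
            kept.append((g, views))
        else:
            dropped += 1
    if dropped:
        logger.info("filtered %d molecules with no breakable bond", dropped)
    return kept, dropped


def split_pretrain(corpus: list, cfg: PretrainConfig) -> tuple[list, list]:
    """Random disjoint train/validation split, reproducible by seed."""
    if len(corpus) < 2:
        raise ValueError("corpus must contain at least 2 molecules")
    n_val = round(cfg.validation_fraction * len(corpus))
    n_val = max(1, min(n_val, len(corpus) - 1))
    order = np.random.default_rng(cfg.seed).permutation(len(corpus))
    val_idx = set(order[:n_val].tolist())
    train = [corpus[i] for i in range(len(corpus)) if i not in val_idx]
    val = [corpus[i] for i in sorted(val_idx)]
    return train, val


def _subsample_views(views, cap, rng):
    if cap is not None and len(views) > cap:
        idx = sorted(rng.choice(len(views), size=cap, replace=False).tolist())
        return [views[i] for i in idx]
    return views


def batch_projections(model: TwoBranchModel, batch, nb_cap=None, rng=None):
    """Projections of both branches plus per-view projections for a batch.

    Returns ``(p_mol, p_fv, p_frag_lists)`` where the first two are (N, d)
    tensors of unit rows and the last is a per-molecule list of unit vectors.
    """
    p_mol_rows, p_fv_rows, p_frag_lists = [], [], []
    for g, views in batch:
        views = _subsample_views(views, nb_cap, rng)
        h_mol, h_frag, _fused, h_fv = model.embed_t(g, views)
        p_mol_rows.append(model.heads["mol"](h_mol))
        p_fv_rows.append(model.heads["fv"](h_fv))
        p_frag_lists.append([model.heads["frag"](h) for h in h_frag])
    return stack_rows(p_mol_rows), stack_rows(p_fv_rows), p_frag_lists


def _batch_loss(model, batch, loss_cfg, nb_cap=None, rng=None):
    p_mol, p_fv, p_frag = batch_projections(model, batch, nb_cap, rng)
    _, _, l_clr = nt_xent_t(p_mol, p_fv, loss_cfg)
    _, l_sim = similarity_loss_t(p_frag)
    total = l_sim * loss_cfg.gamma + l_clr
    return total, float(l_clr.data), float(l_sim.data)


def _epoch_loss(model, data, loss_cfg, batch_size):
    """Total loss over a dataset without gradient tracking (for validation)."""
    tot = 0.0
    for lo in range(0, len(data), batch_size):
        batch = data[lo:lo + batch_size]
        if len(batch) < 2:
            continue
        total, _, _ = _batch_loss(model, batch, loss_cfg)
        tot += float(total.data)
    return tot


def pretrain(corpus: list[MolecularGraph], cfg: PretrainConfig,
             log_path: str | Path | None = None) -> PretrainResult:
    """Pre-train on an unlabeled corpus and return the best-validation model.

    The trace records epoch-level train losses and validation totals; a TSV
    log (step, L_clr, L_sim, total) is written when ``log_path`` is given.
    """
    pairs, _ = filter_corpus(corpus)
    train, val = split_pretrain(pairs, cfg)
    if not train:
        raise ValueError("empty train split")
    model = TwoBranchModel(cfg.encoder)
    opt = Adam(model.params, lr=cfg.learning_rate)
    loss_cfg = cfg.loss_config()
    rng = np.random.default_rng(cfg.seed + 1)

    initial_train_loss = _epoch_loss(model, train, loss_cfg, cfg.batch_size)
    best_state, best_val, best_epoch = model.state_dict(), np.inf, -1
    train_losses, val_losses = [], []
    log_rows = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        ep_clr = ep_sim = ep_total = 0.0
        for lo in range(0, len(train), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            if len(idx) < 2:
                continue
            batch = [train[i] for i in idx]
            opt.zero_grad()
            total, l_clr, l_sim = _batch_loss(model, batch, loss_cfg,
                                              cfg.nb_cap, rng)
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"L_clr={l_clr}, L_sim={l_sim}"
                )
            total.backward()
            opt.step()
            ep_clr += l_clr
            ep_sim += l_sim
            ep_total += float(total.data)
            log_rows.append((step, l_clr, l_sim, float(total.data)))
            step += 1
        train_losses.append({"L_clr": ep_clr, "L_sim": ep_sim, "total": ep_total})
        # a validation set of one molecule has no negatives, so its
        # contrastive loss is undefined; fall back to the train loss
        if len(val) >= 2:
            v = _epoch_loss(model, val, loss_cfg, cfg.batch_size)
        else:
            v = ep_total
        val_losses.append(v)
        if v < best_val:
            best_val, best_epoch, best_state = v, epoch, model.state_dict()
        logger.info("epoch %d: train total %.4f, val total %.4f", epoch,
                    ep_total, v)

    model.load_state_dict(best_state)
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("step\tL_clr\tL_sim\ttotal\n")
            for row in log_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
    return PretrainResult(
        model=model,
        best_epoch=best_epoch,
        best_validation_loss=best_val,
        train_losses=train_losses,
        validation_losses=val_losses,
        initial_train_loss=initial_train_loss,
    )


# ---- diagnostics used by the collapse and alignment checks -------------------


def mean_positive_pair_similarity(model, pairs) -> float:
    """Mean inner product <p_mol_i, p_fv_i> over a list of (graph, views)."""
    sims = []
    for g, views in pairs:
        h_mol, _h_frag, _fused, h_fv = model.embed_t(g, views)
        pm = model.heads["mol"](h_mol).data
        pf = model.heads["fv"](h_fv).data
        sims.append(float(pm @ pf))
    return float(np.mean(sims))


def mean_fragment_projection_variance(model, pairs) -> float:
    """Mean within-molecule variance of the per-view projections.

    Zero iff every molecule's fragment projections coincide — the collapse
    fixed point an over-weighted similarity loss drives the model towards.
    Molecules with a single view are skipped (their variance is trivially 0).
    """
    out = []
    for g, views in pairs:
        if len(views) < 2:
            continue
        _h_mol, h_frag, _fused, _h_fv = model.embed_t(g, views)
        P = np.stack([model.heads["frag"](h).data for h in h_frag])
        out.append(float(P.var(axis=0).sum()))
    return float(np.mean(out)) if out else 0.0
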