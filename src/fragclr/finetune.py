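"""Transfer of a pre-trained model to labeled property-prediction tasks.

Four transfer settings combine two choices: which branch supplies the
molecular representation (``mol`` — the molecule-view embedding ``h_mol``;
``frag`` — the fused fragment-view embedding ``h_fv``) and whether the
pre-trained encoder is fine-tuned (``ft``) or frozen (``fr``) while a fresh
two-layer prediction head is trained on top.  Datasets are split by
Bemis–Murcko scaffold in an 8:1:1 ratio so that test molecules come from
scaffolds never seen in training; classification is scored by ROC-AUC and
regression by RMSE, following the usual molecular-benchmark conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Tensor, stack_rows
from .chem_io import MolecularGraph
from .encoders import TwoBranchModel, _glorot
from .views import all_views

logger = logging.getLogger(__name__)

__all__ = ["TransferSetting", "TaskSpec", "FinetuneConfig", "scaffold_split",
           "finetune", "evaluate", "FinetunedModel"]


@dataclass(frozen=True)
class TransferSetting:
    """One of the four transfer settings: {ft, fr} x {mol, frag}."""

    branch: str  # "mol" or "frag"
    mode: str    # "ft" (fine-tune) or "fr" (freeze)

    def __post_init__(self) -> None:
        if self.branch not in ("mol", "frag"):
            raise ValueError("branch must be 'mol' or 'frag'")
        if self.mode not in ("ft", "fr"):
            raise ValueError("mode must be 'ft' or 'fr'")

    @classmethod
    def parse(cls, text: str) -> "TransferSetting":
        """Parse e.g. ``'ft-frag'`` or ``'fr-mol'``."""
        mode, branch = text.split("-")
        return cls(branch=branch, mode=mode)


@dataclass(frozen=True)
class TaskSpec:
    """Downstream task type and metric (classification↔ROC-AUC, regression↔RMSE)."""

    task_type: str  # "classification" or "regression"
    label_name: str = "label"

    def __post_init__(self) -> None:
        if self.task_type not in ("classification", "regression"):
            raise ValueError("task_type must be 'classification' or 'regression'")

    @property
    def metric(self) -> str:
        return "roc_auc" if self.task_type == "classification" else "rmse"


@dataclass(frozen=True)
class FinetuneConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


def bemis_murcko_scaffold(g: MolecularGraph) -> str:
    return MurckoScaffold.MurckoScaffoldSmiles(mol=g.mol)


def scaffold_split(
    dataset: list[tuple[MolecularGraph, float]],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Bemis–Murcko scaffold split into train/valid/test.

    Scaffold groups are assigned greedily from largest to smallest, filling
    the train budget first, then validation, then test, so no scaffold ever
    spans two splits.  Ties between equal-sized groups are broken by a seeded
    shuffle, making the split reproducible.
    """
    if not dataset:
        raise ValueError("empty dataset")
    groups: dict[str, list[int]] = {}
    for i, (g, _y) in enumerate(dataset):
        groups.setdefault(bemis_murcko_scaffold(g), []).append(i)
    if len(groups) < 3:
        raise ValueError(f"need at least 3 scaffolds, got {len(groups)}")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))  # stable: seeded order breaks ties
    n = len(dataset)
    n_train, n_valid = ratios[0] * n, ratios[1] * n
    splits: tuple[list, list, list] = ([], [], [])
    for k in keys:
        if len(splits[0]) + len(groups[k]) <= round(n_train) or not splits[0]:
            splits[0].extend(groups[k])
        elif len(splits[1]) + len(groups[k]) <= round(n_valid) or not splits[1]:
            splits[1].extend(groups[k])
        else:
            splits[2].extend(groups[k])
    if not splits[2]:
        splits[2].append(splits[1].pop())
    return tuple([dataset[i] for i in sorted(part)] for part in splits)


class PredictionHead:
    """Two-layer feed-forward prediction head on top of a representation."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.params = {
            "W1": Tensor.param(_glorot(rng, d, d)),
            "b1": Tensor.param(np.zeros(d)),
            "W2": Tensor.param(_glorot(rng, d, 1)),
            "b2": Tensor.param(np.zeros(1)),
        }

    def __call__(self, h: Tensor) -> Tensor:
        z = (h @ self.params["W1"] + self.params["b1"]).relu()
        return (z @ self.params["W2"] + self.params["b2"]).reshape(())


@dataclass
class FinetunedModel:
    encoder: TwoBranchModel
    head: PredictionHead
    setting: TransferSetting
    task: TaskSpec

    def representation_t(self, g: MolecularGraph) -> Tensor:
        if self.setting.branch == "mol":
            return self.encoder.encode_molecule_t(g)
        views = all_views(g)
        if not views:
            raise ValueError(f"molecule {g.smiles!r} has no fragment view")
        h_frag = [self.encoder.encode_fragment_pair_t(v) for v in views]
        _fused, h_fv = self.encoder.fuse_views_t(h_frag)
        return h_fv

    def predict_t(self, g: MolecularGraph) -> Tensor:
        return self.head(self.representation_t(g))

    def predict(self, graphs: list[MolecularGraph]) -> np.ndarray:
        return np.array([float(self.predict_t(g).data) for g in graphs])


def _task_loss_t(logits: Tensor, y: np.ndarray, task: TaskSpec) -> Tensor:
    if task.task_type == "classification":
        # binary cross-entropy on logits: softplus(z) - y*z, with a constant
        # shift m = max(z, 0) for numerical stability (gradient unaffected)
        z = logits
        m = np.maximum(z.data, 0.0)
        softplus = ((z - Tensor.const(m)).exp() + Tensor.const(np.exp(-m))).log() \
            + Tensor.const(m)
        return (softplus - Tensor.const(y) * z).sum()
    diff = logits - Tensor.const(y)
    return (diff * diff).sum()


def evaluate(model: FinetunedModel, split: list, task: TaskSpec) -> float:
    """ROC-AUC (classification) or RMSE (regression) on a labeled split."""
    if not split:
        raise ValueError("empty evaluation split")
    graphs = [g for g, _ in split]
    y = np.array([v for _, v in split], dtype=np.float64)
    pred = model.predict(graphs)
    if task.task_type == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("ROC-AUC undefined on a single-class split")
        return float(roc_auc_score(y, pred))
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def finetune(
    model: TwoBranchModel,
    dataset: list[tuple[MolecularGraph, float]],
    setting: TransferSetting,
    task: TaskSpec,
    cfg: FinetuneConfig = FinetuneConfig(),
    splits: tuple[list, list, list] | None = None,
) -> tuple[FinetunedModel, float]:
    """Train a prediction head (optionally fine-tuning the encoder) and
    return the fine-tuned model plus its test metric.

    The encoder is deep-copied, so the caller's checkpoint is never mutated.
    In ``fr`` mode only the head's parameters enter the optimiser, leaving
    every encoder parameter bit-identical.  Model selection uses the
    validation split (highest ROC-AUC / lowest RMSE).
    """
    work = TwoBranchModel(model.cfg)
    work.load_state_dict(model.state_dict())

    if setting.branch == "frag":
        kept = [(g, y) for (g, y) in dataset if all_views(g)]
        rejected = len(dataset) - len(kept)
        if rejected:
            logger.warning(
                "frag branch: rejected %d molecules without fragment views",
                rejected,
            )
        dataset = kept

    if splits is None:
        splits = scaffold_split(dataset, seed=cfg.seed)
    train, valid, test = splits

    rng = np.random.default_rng(cfg.seed)
    head = PredictionHead(model.cfg.embedding_dim, rng)
    fitted = FinetunedModel(encoder=work, head=head, setting=setting, task=task)

    trainable = dict(head.params)
    if setting.mode == "ft":
        trainable.update(work.params)
    opt = Adam(trainable, lr=cfg.learning_rate)

    # ties prefer the later epoch: with small validation splits the metric
    # saturates early while the model is still improving
    better = (lambda a, b: a >= b) if task.task_type == "classification" else (
        lambda a, b: a <= b)
    best_metric, best_state = None, (work.state_dict(),
                                     {k: p.data.copy() for k, p in head.params.items()})
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        for lo in range(0, len(train), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            batch = [train[i] for i in idx]
            y = np.array([v for _, v in batch], dtype=np.float64)
            opt.zero_grad()
            logits = stack_rows([fitted.predict_t(g) for g, _ in batch])
            loss = _task_loss_t(logits, y, task) * (1.0 / len(batch))
            loss.backward()
            opt.step()
        try:
            m = evaluate(fitted, valid, task)
        except ValueError:
            m = None  # single-class validation split: fall back to last epoch
        if m is not None and (best_metric is None or better(m, best_metric)):
            best_metric = m
            best_state = (work.state_dict(),
                          {k: p.data.copy() for k, p in head.params.items()})
    work.load_state_dict(best_state[0])
    for k, p in head.params.items():
        p.data = best_state[1][k]
    return fitted, evaluate(fitted, test, task)
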