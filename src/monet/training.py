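"""Semi-supervised training on the labeled subset of one network.

The forward pass runs over the whole graph, but the class-weighted
cross-entropy is evaluated only on the labeled nodes of the current split.
Cross-validation follows a repeated Monte-Carlo scheme by default: each of
``cv_folds`` repeats draws a fresh stratified 75/25 train/test partition of
the labeled nodes and holds out 10% of the train portion as a validation set
for early stopping. A classic stratified K-fold partition is available via
``cv_scheme="kfold"``. Class imbalance is handled by weighting positive
samples with c = round-half-up(n_neg / n_pos).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import (AttributedGraphDataset, LABEL_NEGATIVE, LABEL_POSITIVE)
from .evaluation import MetricsReport, metrics_report
from .gnn_core import MonetModel, normalize_adjacency, self_loop_edge_index

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "SplitPlan", "FoldResult", "CVReport",
    "compute_class_weight", "weighted_bce_loss", "make_splits",
    "train_fold", "run_cross_validation", "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults follow the reference protocol: GCN hidden dims 300/100 with a
    16-dimensional output, GAT hidden width 100 with 5 heads plus one
    16-dimensional output head, an MLP with one 16-unit hidden layer, Adam at
    learning rate 1e-3 with weight decay 5e-4, dropout 0.5, at most 2000
    epochs with validation-loss early stopping, ten cross-validation repeats
    of a stratified 75/25 split.
    """

    gcn_dims: tuple[int, ...] = (300, 100, 16)
    gat_hidden_dim: int = 100
    gat_heads_hidden: int = 5
    gat_heads_out: int = 1
    gat_out_dim: int = 16
    mlp_hidden: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    dropout: float = 0.5
    max_epochs: int = 2000
    patience: int = 100
    seed: int = 0
    cv_folds: int = 10
    test_fraction: float = 0.25
    val_fraction: float = 0.10
    cv_scheme: str = "montecarlo"  # or "kfold"
    branch: str = "both"  # "both" | "gcn" | "gat"

    def __post_init__(self):
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_scheme not in ("montecarlo", "kfold"):
            raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")
        if any(d <= 0 for d in self.gcn_dims):
            raise ValueError("all dims must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Key-value config file (YAML syntax); every key optional."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gcn_dims" in raw:
            raw["gcn_dims"] = tuple(raw["gcn_dims"])
        return cls(**raw)

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SplitRepeat:
    """One repeat: node-index arrays for train/validation/test."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass(frozen=True)
class SplitPlan:
    repeats: tuple[SplitRepeat, ...]
    seed: int


@dataclass
class FoldResult:
    fold: int
    probs: np.ndarray  # per-node, all nodes
    metrics: MetricsReport  # on the test set
    epochs_run: int
    best_val_loss: float


@dataclass
class CVReport:
    folds: list[FoldResult]
    metrics_mean: dict[str, float]
    metrics_std: dict[str, float]
    avg_probs: np.ndarray  # fold-averaged, per node

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def compute_class_weight(n_pos: int, n_neg: int) -> int:
    """Positive-class weight c = round-half-up(n_neg / n_pos), at least 1."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one sample")
    ratio = n_neg / n_pos
    return max(1, int(np.floor(ratio + 0.5)))


def weighted_bce_loss(probs, y, c: float, mask) -> float:
    """Mean of -[c*y*log(p) + (1-y)*log(1-p)] over the masked nodes."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    p = np.clip(probs[mask], 1e-12, 1 - 1e-12)
    t = y[mask]
    return float(np.mean(-(c * t * np.log(p) + (1 - t) * np.log(1 - p))))


def _masked_loss_t(logits: Tensor, y01: np.ndarray, c: float,
                   mask: np.ndarray) -> Tensor:
    """Autodiff version of the weighted loss, stable in the logits.

    Uses -y log sigmoid(x) = y softplus(-x) and
    -(1-y) log(1-sigmoid(x)) = (1-y) softplus(x).
    """
    idx = np.flatnonzero(mask)
    x = ad.gather_rows(logits, idx)
    t = y01[idx].reshape(-1, 1).astype(float)
    pos_term = ad.mul(ad.softplus(ad.neg(x)), Tensor(c * t))
    neg_term = ad.mul(ad.softplus(x), Tensor(1.0 - t))
    return ad.mean_(ad.add(pos_term, neg_term))


def make_splits(y: np.ndarray, config: ModelConfig) -> SplitPlan:
    """Stratified train/validation/test assignments of the labeled nodes.

    Monte-Carlo scheme: ``cv_folds`` independent stratified
    (1 - test_fraction)/test_fraction shuffles, each seeded from the run
    seed and the repeat index. K-fold scheme: a single stratified partition
    into ``cv_folds`` test folds. In both, ``val_fraction`` of each train
    portion is held out for early stopping.
    """
    labeled = np.flatnonzero(y != -1)
    classes = y[labeled]
    n_pos = int(np.sum(classes == LABEL_POSITIVE))
    n_neg = int(np.sum(classes == LABEL_NEGATIVE))
    if min(n_pos, n_neg) < config.cv_folds:
        raise ValueError(
            f"need at least cv_folds={config.cv_folds} labeled nodes per "
            f"class, got {n_pos} positives / {n_neg} negatives")
    repeats = []
    if config.cv_scheme == "montecarlo":
        for r in range(config.cv_folds):
            sss = StratifiedShuffleSplit(
                n_splits=1, test_size=config.test_fraction,
                random_state=(config.seed * 1009 + r) % (2**31 - 1))
            (tr, te), = sss.split(labeled.reshape(-1, 1), classes)
            repeats.append(_with_validation(labeled, classes, tr, te,
                                            config, r))
    else:
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=config.seed % (2**31 - 1))
        for r, (tr, te) in enumerate(skf.split(labeled.reshape(-1, 1),
                                               classes)):
            repeats.append(_with_validation(labeled, classes, tr, te,
                                            config, r))
    return SplitPlan(repeats=tuple(repeats), seed=config.seed)


def _with_validation(labeled, classes, tr, te, config, r) -> SplitRepeat:
    sss = StratifiedShuffleSplit(
        n_splits=1, test_size=config.val_fraction,
        random_state=(config.seed * 2003 + r) % (2**31 - 1))
    (tr2, va), = sss.split(tr.reshape(-1, 1), classes[tr])
    return SplitRepeat(train_idx=np.sort(labeled[tr[tr2]]),
                       val_idx=np.sort(labeled[tr[va]]),
                       test_idx=np.sort(labeled[te]))


class _Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _node_mask(n: int, idx: np.ndarray) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[idx] = True
    return m


def train_fold(dataset: AttributedGraphDataset, split: SplitRepeat,
               config: ModelConfig, fold: int = 0,
               log_path: str | Path | None = None) -> FoldResult:
    """Train on one split repeat and evaluate on its test set.

    Adam on the masked weighted loss; stops when the validation loss has not
    improved for ``patience`` epochs or at ``max_epochs``, restoring the
    best-validation parameters. Returns probabilities for every node from
    the restored model.
    """
    n = dataset.n_nodes
    y01 = np.where(dataset.y == LABEL_POSITIVE, 1, 0)
    train_mask = _node_mask(n, split.train_idx)
    val_mask = _node_mask(n, split.val_idx)
    labeled = dataset.y != -1
    c = compute_class_weight(int(np.sum(dataset.y[labeled] == 1)),
                             int(np.sum(dataset.y[labeled] == 0)))

    fold_seed = (config.seed * 9176 + fold) % (2**31 - 1)
    model = MonetModel(
        d_in=dataset.features.shape[1], gcn_dims=tuple(config.gcn_dims),
        gat_hidden_dim=config.gat_hidden_dim,
        gat_heads_hidden=config.gat_heads_hidden,
        gat_out_dim=config.gat_out_dim, mlp_hidden=config.mlp_hidden,
        dropout=config.dropout, branch=config.branch, seed=fold_seed)
    dropout_rng = np.random.default_rng(fold_seed + 1)
    opt = _Adam(model.parameters(), config.learning_rate, config.weight_decay)

    adj_norm = normalize_adjacency(dataset.network)
    edge_index = self_loop_edge_index(dataset.network)
    X = dataset.features

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    log_lines: list[str] = []
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        opt.zero_grad()
        logits = model.forward_logits(X, adj_norm, edge_index,
                                      dropout_rng=dropout_rng)
        loss = _masked_loss_t(logits, y01, c, train_mask)
        if not np.isfinite(loss.data):
            raise TrainingDivergedError(
                f"training loss became non-finite at epoch {epoch}")
        loss.backward()
        opt.step()

        eval_logits = model.forward_logits(X, adj_norm, edge_index)
        val_loss = float(_masked_loss_t(eval_logits, y01, c, val_mask).data)
        log_lines.append(f"epoch={epoch}\ttrain_loss={float(loss.data):.6f}"
                         f"\tval_loss={val_loss:.6f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            log_lines.append(f"stop=early\tbest_epoch={best_epoch}")
            break
    else:
        log_lines.append(f"stop=max_epochs\tbest_epoch={best_epoch}")

    model.load_state_dict(best_state)
    probs = model.predict_proba(dataset)
    test_mask = _node_mask(n, split.test_idx)
    report = metrics_report(y01[test_mask], probs[test_mask])
    if log_path is not None:
        Path(log_path).write_text("\n".join(log_lines) + "\n")
    return FoldResult(fold=fold, probs=probs, metrics=report,
                      epochs_run=epoch, best_val_loss=best_val)


def run_cross_validation(dataset: AttributedGraphDataset,
                         config: ModelConfig,
                         log_dir: str | Path | None = None) -> CVReport:
    """All CV repeats; per-metric mean/std over fold test sets and
    fold-averaged per-node probabilities (used for gene ranking)."""
    plan = make_splits(dataset.y, config)
    folds = []
    for r, split in enumerate(plan.repeats):
        log_path = (Path(log_dir) / f"fold_{r}.log") if log_dir else None
        folds.append(train_fold(dataset, split, config, fold=r,
                                log_path=log_path))
        logger.info("fold %d: AUROC=%.4f AUPR=%.4f (%d epochs)", r,
                    folds[-1].metrics.auroc, folds[-1].metrics.aupr,
                    folds[-1].epochs_run)
    keys = ["ACC", "AUROC", "AUPR", "F1", "MCC"]
    values = {k: np.array([f.metrics.as_dict()[k] for f in folds])
              for k in keys}
    return CVReport(
        folds=folds,
        metrics_mean={k: float(v.mean()) for k, v in values.items()},
        metrics_std={k: float(v.std(ddof=0)) for k, v in values.items()},
        avg_probs=np.mean([f.probs for f in folds], axis=0),
    )


def write_probabilities(dataset: AttributedGraphDataset, probs: np.ndarray,
                        n_folds: int, path: str | Path) -> None:
    """TSV: gene, fold-averaged probability, label, fold count."""
    label_names = {1: "positive", 0: "negative", -1: "unlabeled"}
    with Path(path).open("w") as fh:
        fh.write("gene\tprobability\tlabel\tfold_count\n")
        for gene, p, yi in zip(dataset.network.nodes, probs, dataset.y):
            fh.write(f"{gene}\t{p:.10g}\t{label_names[int(yi)]}\t{n_folds}\n")
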