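"""Classification metrics for imbalanced gene-label sets.

Threshold metrics (accuracy, F1, Matthews correlation coefficient) are
computed directly from the confusion counts; ranking metrics (AUROC, AUPR)
and their curves are delegated to scikit-learn, with AUPR using the
step-wise non-interpolated convention (average precision). Degenerate
denominators in F1/MCC yield 0 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

__all__ = [
    "ConfusionCounts", "MetricsReport", "Curve",
    "confusion_counts", "classification_metrics", "auroc", "aupr",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Curve:
    """An ordered ROC or PR curve as (x, y) points."""

    x: np.ndarray
    y: np.ndarray
    kind: str  # "roc" | "pr"


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    auroc: float
    aupr: float
    f1: float
    mcc: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "AUROC": self.auroc, "AUPR": self.aupr,
                "F1": self.f1, "MCC": self.mcc}


def confusion_counts(y, probs, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with prediction = (prob >= threshold)."""
    y = np.asarray(y).astype(int)
    probs = np.asarray(probs, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != probs.shape:
        raise ValueError("labels and scores must have the same length")
    pred = probs >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def classification_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, F1, MCC) from a confusion table.

    ACC = (TP+TN)/(TP+FP+TN+FN); F1 = 2PR/(P+R) with
    P = TP/(TP+FP), R = TP/(TP+FN); MCC = (TP*TN - FP*FN) /
    sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Any zero denominator factor gives 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    acc = (tp + tn) / total if total else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return acc, f1, mcc


def auroc(y, scores) -> tuple[float, Curve]:
    """Area under the ROC (TPR = TP/(TP+FN) vs FPR = FP/(FP+TN)).

    Ties follow the rank/trapezoid convention, so the area equals the
    normalized Mann-Whitney U statistic. Requires both classes present.
    """
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, scores)
    return float(roc_auc_score(y, scores)), Curve(x=fpr, y=tpr, kind="roc")


def aupr(y, scores) -> tuple[float, Curve]:
    """Area under precision-recall, step-wise (non-interpolated)."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not (y == 1).any():
        raise ValueError("AUPR requires at least one positive")
    precision, recall, _ = precision_recall_curve(y, scores)
    return float(average_precision_score(y, scores)), Curve(
        x=recall[::-1], y=precision[::-1], kind="pr")


def metrics_report(y, probs, threshold: float = 0.5) -> MetricsReport:
    """Full metric suite on one evaluation set."""
    counts = confusion_counts(y, probs, threshold)
    acc, f1, mcc = classification_metrics(counts)
    roc_area, _ = auroc(y, probs)
    pr_area, _ = aupr(y, probs)
    return MetricsReport(acc=acc, auroc=roc_area, aupr=pr_area, f1=f1,
                         mcc=mcc, threshold=threshold)


def write_metrics_tsv(reports: dict[str, MetricsReport], path) -> None:
    """One row per named report, columns ACC/AUROC/AUPR/F1/MCC."""
    with open(path, "w") as fh:
        fh.write("name\tACC\tAUROC\tAUPR\tF1\tMCC\n")
        for name, r in reports.items():
            fh.write(f"{name}\t{r.acc:.6f}\t{r.auroc:.6f}\t{r.aupr:.6f}"
                     f"\t{r.f1:.6f}\t{r.mcc:.6f}\n")


def write_curve_tsv(curve: Curve, path) -> None:
    header = {"roc": "fpr\ttpr", "pr": "recall\tprecision"}[curve.kind]
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for x, y in zip(curve.x, curve.y):
            fh.write(f"{x:.10g}\t{y:.10g}\n")
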