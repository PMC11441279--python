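"""Binary classification metrics for link prediction.

Confusion-based metrics (recall/TPR, precision, specificity, accuracy, F1) at
a fixed score threshold, plus area under the ROC curve and under the
precision-recall curve, both by trapezoidal integration of the curves over
every distinct score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError

__all__ = ["FoldMetrics", "MetricsReport", "compute_metrics", "roc_curve_points", "pr_curve_points"]

METRIC_NAMES = ("auc", "aupr", "f1", "acc", "recall", "specificity", "precision")


@dataclass(frozen=True)
class FoldMetrics:
    auc: float
    aupr: float
    f1: float
    acc: float
    recall: float
    specificity: float
    precision: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold metrics with mean and standard deviation, plus fold assignment."""

    folds: tuple[FoldMetrics, ...]
    fold_assignment: np.ndarray
    seed: int

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(f, name) for f in self.folds]))

    def std(self, name: str) -> float:
        return float(np.std([getattr(f, name) for f in self.folds]))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {name: (self.mean(name), self.std(name)) for name in METRIC_NAMES}


def _validate(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise EvaluationError("labels and scores must be 1-D arrays of equal length")
    if not np.isin(labels, (0, 1)).all():
        raise EvaluationError("labels must be binary")
    if labels.min() == labels.max():
        raise EvaluationError("AUC undefined: labels contain a single class")
    return labels.astype(np.int64), scores


def roc_curve_points(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points swept over every distinct score threshold, ties pooled."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.r_[distinct, y.size - 1]
    tp = np.cumsum(y)[cut].astype(np.float64)
    fp = np.cumsum(1 - y)[cut].astype(np.float64)
    tpr = np.r_[0.0, tp / tp[-1]]
    fpr = np.r_[0.0, fp / fp[-1]]
    return fpr, tpr

def pr_curve_points(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) points over every distinct threshold, ties pooled."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.r_[distinct, y.size - 1]
    tp = np.cumsum(y)[cut].astype(np.float64)
    fp = np.cumsum(1 - y)[cut].astype(np.float64)
    recall = tp / y.sum()
    precision = tp / (tp + fp)
    # anchor at recall 0 with the first observed precision
    return np.r_[0.0, recall], np.r_[precision[0], precision]


def compute_metrics(labels, scores, threshold: float = 0.5) -> FoldMetrics:
    """All seven metrics for one score vector."""
    labels, scores = _validate(np.asarray(labels), np.asarray(scores))
    pred = (scores >= threshold).astype(np.int64)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())

    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )

    fpr, tpr = roc_curve_points(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    rec_pts, prec_pts = pr_curve_points(labels, scores)
    aupr = float(np.trapezoid(prec_pts, rec_pts))
    return FoldMetrics(
        auc=auc,
        aupr=aupr,
        f1=f1,
        acc=acc,
        recall=recall,
        specificity=specificity,
        precision=precision,
    )
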