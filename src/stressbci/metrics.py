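"""Confusion matrices and one-vs-rest class-wise metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_curve as _sk_pr_curve

from .session import CONDITIONS


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...] = CONDITIONS

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)


def confusion(
    y_true, y_pred, labels: tuple[str, ...] = CONDITIONS
) -> ConfusionMatrix:
    """Count matrix of true vs predicted integer class ids."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    k = len(labels)
    for v in (y_true, y_pred):
        if v.size and (v.min() < 0 or v.max() >= k):
            raise ValueError(f"labels must be integer ids in 0..{k - 1}")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(k))
    return ConfusionMatrix(counts=counts, labels=labels)


@dataclass
class EvalReport:
    """Overall and one-vs-rest class-wise rates.

    Undefined rates (empty class row/column) are ``nan``, never 0.
    """

    accuracy: float
    sensitivity: dict[str, float]  # = recall = per-class accuracy
    specificity: dict[str, float]
    precision: dict[str, float]


def classwise_report(cm: ConfusionMatrix) -> EvalReport:
    """One-vs-rest sensitivity, specificity and precision per class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    total = c.sum()
    sens, spec, prec = {}, {}, {}
    for i, name in enumerate(cm.labels):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[name] = tp / (tp + fn) if tp + fn > 0 else float("nan")
        spec[name] = tn / (tn + fp) if tn + fp > 0 else float("nan")
        prec[name] = tp / (tp + fp) if tp + fp > 0 else float("nan")
    return EvalReport(
        accuracy=cm.accuracy, sensitivity=sens, specificity=spec, precision=prec
    )


def precision_recall_points(
    y_true, scores, labels: tuple[str, ...] = CONDITIONS
) -> dict[str, np.ndarray]:
    """One-vs-rest precision-recall curve points per class.

    ``scores`` is the (n, k) matrix of per-window class scores; each entry
    of the result is an array of (precision, recall) rows.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    out = {}
    for i, name in enumerate(labels):
        if not (y_true == i).any():
            out[name] = np.empty((0, 2))
            continue
        p, r, _ = _sk_pr_curve(y_true == i, scores[:, i])
        out[name] = np.column_stack([p, r])
    return out
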