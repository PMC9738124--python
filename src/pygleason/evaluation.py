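"""Confusion matrices, one-vs-rest precision/recall/F1, and ROC curves."""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ConfusionMatrix", "ClassMetrics", "confusion", "metrics", "roc_curve"]


@dataclasses.dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = actual, columns = predicted
    class_labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be KxK with K = len(class_labels)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row_percentages(self) -> np.ndarray:
        """Row-normalized view (percent of each actual class), 0 rows stay 0."""
        sums = self.supports.astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums[:, None] > 0, self.counts / sums[:, None] * 100.0, 0.0)
        return pct


def confusion(actual: Sequence, predicted: Sequence, class_labels: Sequence | None = None) -> ConfusionMatrix:
    """Count matrix with rows = actual and columns = predicted labels."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    if class_labels is None:
        class_labels = sorted(set(actual) | set(predicted))
    class_labels = list(class_labels)
    index = {lab: i for i, lab in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"label outside the class set: {a!r} / {p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_labels=class_labels)


@dataclasses.dataclass
class ClassMetrics:
    class_labels: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_avg: dict  # unweighted means
    weighted_avg: dict  # support-weighted means

    def to_frame(self):
        import pandas as pd

        rows = {
            str(lab): {
                "precision": self.precision[i],
                "recall": self.recall[i],
                "f1": self.f1[i],
                "support": int(self.support[i]),
            }
            for i, lab in enumerate(self.class_labels)
        }
        rows["macro_avg"] = {**self.macro_avg, "support": int(self.support.sum())}
        rows["weighted_avg"] = {**self.weighted_avg, "support": int(self.support.sum())}
        return pd.DataFrame(rows).T


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    zero = den == 0
    if zero.any():
        warnings.warn(f"zero denominator in {what}; reporting 0", stacklevel=3)
    np.divide(num, den, out=out, where=~zero)
    return out


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest precision/recall/F1 per class, plus accuracy and averages.

    recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = 2PR/(P+R); classes with
    a zero denominator report 0 with a warning.  The macro average is the
    unweighted mean of per-class values; the weighted average weights each
    class by its support.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts).astype(np.float64)
    fn = cm.counts.sum(axis=1) - tp
    fp = cm.counts.sum(axis=0) - tp
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    support = cm.supports
    accuracy = float(tp.sum() / cm.total)
    weights = support / support.sum()
    macro = {
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }
    weighted = {
        "precision": float((precision * weights).sum()),
        "recall": float((recall * weights).sum()),
        "f1": float((f1 * weights).sum()),
    }
    return ClassMetrics(
        class_labels=list(cm.class_labels),
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        accuracy=accuracy,
        macro_avg=macro,
        weighted_avg=weighted,
    )


def roc_curve(scores: Sequence[float], truths: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """TPR/FPR sweep and trapezoidal area for binary scores.

    ``scores`` are positive-class probabilities; ``truths`` are 0/1 labels.
    Returns ``(fpr, tpr, thresholds, auc)``.
    """
    truths = np.asarray(truths, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(truths)) < 2:
        raise ValueError("ROC needs both classes present in the truth labels")
    fpr, tpr, thr = _sk_roc_curve(truths, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, auc
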