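"""Multi-class evaluation metrics.

Accuracy, precision, recall and F1 are computed from a confusion matrix
with rows = true class and columns = predicted class.  Precision, recall
and F1 are one-vs-rest per class (TP the diagonal entry, FP the rest of
the column, FN the rest of the row); accuracy is trace / total, and the
report aggregates per-class scores as unweighted (macro) and
support-weighted means.  A metric whose denominator is zero is defined
as 0 and flagged degenerate rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "ClassificationReport",
    "confusion_matrix",
    "accuracy",
    "precision_recall_f1",
    "report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("confusion matrix must hold nonnegative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) tallies treating ``class_index`` as positive."""
        c = self.counts
        tp = int(c[class_index, class_index])
        fp = int(c[:, class_index].sum()) - tp
        fn = int(c[class_index, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)


class ClassMetrics(NamedTuple):
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


@dataclass(frozen=True)
class ClassificationReport:
    class_names: tuple[str, ...]
    per_class: dict[str, ClassMetrics]
    supports: dict[str, int]
    accuracy: float
    macro: ClassMetrics
    weighted: ClassMetrics

    def to_dict(self) -> dict:
        doc = {name: {"precision": m.precision, "recall": m.recall,
                      "f1": m.f1, "support": self.supports[name],
                      "degenerate": m.degenerate}
               for name, m in self.per_class.items()}
        doc["accuracy"] = self.accuracy
        doc["macro_avg"] = {"precision": self.macro.precision,
                            "recall": self.macro.recall, "f1": self.macro.f1}
        doc["weighted_avg"] = {"precision": self.weighted.precision,
                               "recall": self.weighted.recall,
                               "f1": self.weighted.f1}
        return doc


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label sequences must be equal-length 1-D")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if len(y) and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels out of range 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN summed over classes collapses to) trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(cm: ConfusionMatrix, class_index: int) -> ClassMetrics:
    if not 0 <= class_index < cm.n_classes:
        raise IndexError(f"class index {class_index} out of range")
    tp, _, fp, fn = cm.one_vs_rest(class_index)
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return ClassMetrics(precision, recall, _f1(precision, recall), degenerate)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    return _f1(precision, recall)


def report(cm: ConfusionMatrix, class_names) -> ClassificationReport:
    class_names = tuple(class_names)
    if len(class_names) != cm.n_classes:
        raise ValueError("one name per class required")
    per_class = {name: precision_recall_f1(cm, i)
                 for i, name in enumerate(class_names)}
    supports = {name: int(s) for name, s in zip(class_names, cm.supports)}
    metrics = np.array([[m.precision, m.recall, m.f1]
                        for m in per_class.values()])
    weights = cm.supports / cm.total
    macro = ClassMetrics(*metrics.mean(axis=0), degenerate=any(
        m.degenerate for m in per_class.values()))
    weighted = ClassMetrics(*(weights @ metrics), degenerate=macro.degenerate)
    return ClassificationReport(class_names=class_names, per_class=per_class,
                                supports=supports, accuracy=accuracy(cm),
                                macro=macro, weighted=weighted)
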