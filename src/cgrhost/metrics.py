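"""Multi-class evaluation: accuracy, macro precision/recall/F1, top-k
accuracy, and confusion matrices.

Host prediction is a multi-class problem with many rare classes, so
class-balanced (macro) averages are reported alongside plain accuracy:
per-class precision TP_i/(TP_i+FP_i) and recall TP_i/(TP_i+FN_i) are
averaged with equal class weight, and F1 is the per-class harmonic mean
averaged the same way.  A per-class ratio with a zero denominator (a class
never predicted, or absent from the truth) counts as 0 in the macro mean —
the convention is documented rather than inherited silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "accuracy",
    "macro_metrics",
    "topk_accuracy",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    labels: tuple[str, ...]
    matrix: np.ndarray  # (n, n) non-negative ints

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if (self.matrix < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_tsv(self) -> str:
        """Tab-separated grid with a header row/column of taxon names."""
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.matrix):
            lines.append(lab + "\t" + "\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    top_k: Mapping[int, float]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "top_k": {str(k): v for k, v in self.top_k.items()},
        }


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Confusion matrix over the sorted union of observed labels (or an
    explicit label list, e.g. to include classes absent from the test set)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    if len(true_labels) == 0:
        raise ValueError("no predictions to score")
    if labels is None:
        labels = sorted(set(true_labels) | set(predicted_labels))
    cm = _sk_confusion(true_labels, predicted_labels, labels=list(labels))
    return ConfusionMatrix(labels=tuple(labels), matrix=cm)


def accuracy(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> float:
    """Fraction of predictions equal to the truth."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    if len(true_labels) == 0:
        raise ValueError("no predictions to score")
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    return float((t == p).mean())


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(macro precision, macro recall, macro F1) from a confusion matrix.

    Zero-denominator per-class ratios contribute 0 to the macro mean.
    """
    m = cm.matrix.astype(np.float64)
    if m.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    return float(precision.mean()), float(recall.mean()), float(f1.mean())


def topk_accuracy(
    true_labels: Sequence[str],
    ranked_predictions: Sequence[Sequence[str]],
    k_values: Sequence[int] = (1, 5, 10, 15, 20),
) -> dict[int, float]:
    """Fraction of items whose true class is among the first k ranks.

    Rank lists shorter than k are used in full (a list covering all classes
    therefore yields 1.0 once k >= n_classes).  Top-1 equals accuracy.
    """
    if len(true_labels) != len(ranked_predictions):
        raise ValueError("label vectors differ in length")
    if len(true_labels) == 0 or any(len(r) == 0 for r in ranked_predictions):
        raise ValueError("empty rank lists")
    out: dict[int, float] = {}
    for k in k_values:
        hits = sum(
            1
            for t, ranks in zip(true_labels, ranked_predictions)
            if t in list(ranks)[:k]
        )
        out[int(k)] = hits / len(true_labels)
    return out


def evaluate_predictions(
    true_labels: Sequence[str],
    ranked_predictions: Sequence[Sequence[str]],
    k_values: Sequence[int] = (1, 5, 10, 15, 20),
    labels: Sequence[str] | None = None,
) -> MetricReport:
    """Full report from ranked per-item predictions (best first)."""
    top1 = [list(r)[0] for r in ranked_predictions]
    cm = confusion(true_labels, top1, labels=labels)
    prec, rec, f1 = macro_metrics(cm)
    return MetricReport(
        accuracy=accuracy(true_labels, top1),
        macro_precision=prec,
        macro_recall=rec,
        macro_f1=f1,
        top_k=topk_accuracy(true_labels, ranked_predictions, k_values),
    )
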