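"""Confusion matrices and per-class classification metrics.

Orientation convention: rows index the true class, columns the predicted
class. Metrics with a zero denominator are reported as ``None``
(undefined), never silently coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    class_labels: tuple
    counts: np.ndarray  # rows = true, columns = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "counts": self.counts.tolist(),
        }


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]


@dataclass(frozen=True)
class ClassificationReport:
    class_labels: tuple
    per_class: dict
    overall_accuracy: float
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class": {
                str(c): vars(m).copy() for c, m in self.per_class.items()
            },
            "confusion": self.confusion.to_dict(),
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per class: sensitivity, specificity, precision, f1."""
        rows = [
            {
                "class": str(c),
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
                "f1": m.f1,
            }
            for c, m in self.per_class.items()
        ]
        return pd.DataFrame(rows)


def confusion_matrix(true_labels, predicted_labels, class_order=None) -> ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape[0]} true vs {p.shape[0]} predicted")
    if class_order is None:
        class_order = sorted(set(t) | set(p))
    class_order = list(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for ti, pi in zip(t, p):
        if ti not in index:
            raise ValueError(f"true label {ti!r} not in class order")
        if pi not in index:
            raise ValueError(f"predicted label {pi!r} not in class order")
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(tuple(class_order), counts)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def per_class_metrics(cm: ConfusionMatrix) -> ClassificationReport:
    """Sensitivity, specificity, precision and F1 for every class.

    For class c: TP = counts[c, c], FN = row sum − TP, FP = column sum − TP,
    TN = the rest. F1 is the harmonic mean of precision and sensitivity and
    is undefined whenever either is undefined or both are zero.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for i, c in enumerate(cm.class_labels):
        tp = int(counts[i, i])
        fn = int(counts[i].sum()) - tp
        fp = int(counts[:, i].sum()) - tp
        tn = total - tp - fn - fp
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        prec = _ratio(tp, tp + fp)
        if sens is None or prec is None or (sens + prec) == 0:
            f1 = None
        else:
            f1 = 2 * prec * sens / (prec + sens)
        per_class[c] = ClassMetrics(sens, spec, prec, f1)
    return ClassificationReport(
        class_labels=cm.class_labels,
        per_class=per_class,
        overall_accuracy=float(np.trace(counts)) / total,
        confusion=cm,
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total of the confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total
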