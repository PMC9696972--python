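"""Confusion-matrix classification metrics.

Per-class precision tp/(tp+fp), recall tp/(tp+fn), F1 2*pr*rc/(pr+rc) and
one-vs-rest accuracy (tp+tn)/total, plus overall accuracy trace/total.
A metric whose denominator is zero is reported as ``None`` (missing), never
silently as 0, so averages over classes stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "class_counts",
    "precision",
    "recall",
    "f1",
    "accuracy",
    "overall_accuracy",
    "metrics_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i, j] = items of true class labels[i] predicted as labels[j]."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = len(self.labels)
        if c.shape != (n, n):
            raise ValueError(f"counts shape {c.shape} does not match {n} labels")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))

    def index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown class {label!r}") from None


def confusion(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionMatrix:
    """Tally a confusion matrix; label order is sorted distinct labels."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    if len(true_labels) == 0:
        raise ValueError("empty label sequences")
    labels = tuple(sorted(set(true_labels) | set(predicted_labels)))
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def class_counts(cm: ConfusionMatrix, label) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) for one class, one-vs-rest."""
    i = cm.index(label)
    c = np.asarray(cm.counts)
    tp = int(c[i, i])
    fp = int(c[:, i].sum() - tp)
    fn = int(c[i, :].sum() - tp)
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def precision(cm: ConfusionMatrix, label) -> float | None:
    tp, fp, _, _ = class_counts(cm, label)
    return _ratio(tp, tp + fp)


def recall(cm: ConfusionMatrix, label) -> float | None:
    tp, _, fn, _ = class_counts(cm, label)
    return _ratio(tp, tp + fn)


def f1(cm_or_pr, label_or_rc=None) -> float | None:
    """F1 as the harmonic mean of precision and recall.

    Accepts either (ConfusionMatrix, label) or raw (precision, recall).
    Missing precision/recall, or pr + rc == 0, yields None.
    """
    if isinstance(cm_or_pr, ConfusionMatrix):
        pr, rc = precision(cm_or_pr, label_or_rc), recall(cm_or_pr, label_or_rc)
    else:
        pr, rc = cm_or_pr, label_or_rc
    if pr is None or rc is None or pr + rc == 0:
        return None
    return 2.0 * pr * rc / (pr + rc)


def accuracy(cm: ConfusionMatrix, label) -> float | None:
    """One-vs-rest accuracy (tp + tn) / total for one class."""
    tp, fp, fn, tn = class_counts(cm, label)
    return _ratio(tp + tn, tp + fp + fn + tn)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    return float(np.trace(cm.counts) / cm.total)


def metrics_table(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class tp/fp/fn/tn and pr/rc/f1/accuracy as a DataFrame
    (missing metrics appear as NaN)."""
    rows = []
    for lab in cm.labels:
        tp, fp, fn, tn = class_counts(cm, lab)
        rows.append(
            {
                "class": lab,
                "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                "precision": precision(cm, lab),
                "recall": recall(cm, lab),
                "f1": f1(cm, lab),
                "accuracy": accuracy(cm, lab),
            }
        )
    return pd.DataFrame(rows).set_index("class")
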