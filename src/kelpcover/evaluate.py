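"""Confusion-matrix metrics and paired classifier comparison.

Four criteria are reported for every experiment: overall accuracy, mean
f1-score (the arithmetic mean of per-class f1 over the classes present in
the test data), and the precision and recall of a focal class (kelp).
Accuracy alone is misleading under the heavy class skew typical of benthic
point annotations, which is why the mean f1 is carried alongside it: a flat
classifier over a long tail of rare taxa can post high accuracy while its
mean f1 collapses toward zero.

f1 is the harmonic mean of precision and recall,
``f1 = 2 * P * R / (P + R)``, with every 0/0 defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "PairedTestResult",
    "confusion",
    "precision_recall_f1",
    "metrics_report",
    "paired_correctness_test",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are true classes, columns predicted."""

    classes: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({k}, {k})"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, cls) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise KeyError(f"class {cls!r} not in confusion matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class MetricsReport:
    """The four evaluation criteria plus the per-class breakdown."""

    accuracy: float
    per_class: Mapping[str, tuple[float, float, float]]  # precision, recall, f1
    mean_f1: float
    focal_class: str | None
    focal_precision: float | None
    focal_recall: float | None
    focal_f1: float | None
    n_eval: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mean_f1": self.mean_f1,
            "focal_class": self.focal_class,
            "focal_precision": self.focal_precision,
            "focal_recall": self.focal_recall,
            "focal_f1": self.focal_f1,
            "n_eval": self.n_eval,
            "per_class": {
                str(c): {"precision": p, "recall": r, "f1": f}
                for c, (p, r, f) in self.per_class.items()
            },
        }


def confusion(true_labels: Sequence, pred_labels: Sequence) -> ConfusionMatrix:
    """Count matrix over the sorted union of observed labels."""
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    if len(true_labels) != len(pred_labels):
        raise ValidationError(
            f"length mismatch: {len(true_labels)} true vs {len(pred_labels)} predicted"
        )
    if len(true_labels) == 0:
        raise ValidationError("no labels to evaluate")
    classes = sorted(set(true_labels) | set(pred_labels))
    pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(classes, counts)


def precision_recall_f1(cm: ConfusionMatrix, cls) -> tuple[float, float, float]:
    """Precision, recall and f1 of one class; any 0/0 is defined as 0."""
    i = cm.index(cls)
    tp = cm.counts[i, i]
    fp = cm.counts[:, i].sum() - tp
    fn = cm.counts[i, :].sum() - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return float(precision), float(recall), float(f1)


def metrics_report(cm: ConfusionMatrix, focal: str | None = None) -> MetricsReport:
    """Accuracy, per-class P/R/f1, mean f1 and the focal class's scores.

    Mean f1 averages over every class with at least one true or predicted
    instance (all classes of the matrix, by construction).
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    per_class = {c: precision_recall_f1(cm, c) for c in cm.classes}
    mean_f1 = float(np.mean([f for (_, _, f) in per_class.values()]))
    accuracy = float(np.trace(cm.counts) / cm.total)
    focal_p = focal_r = focal_f = None
    if focal is not None:
        focal_p, focal_r, focal_f = per_class.get(focal, (0.0, 0.0, 0.0))
    return MetricsReport(
        accuracy=accuracy,
        per_class=per_class,
        mean_f1=mean_f1,
        focal_class=focal,
        focal_precision=focal_p,
        focal_recall=focal_r,
        focal_f1=focal_f,
        n_eval=cm.total,
    )


@dataclass
class PairedTestResult:
    """Paired t-test between two classifiers' per-point correctness."""

    n_sampled: int
    mean_difference: float
    t_statistic: float
    p_value: float
    seed: int
    degenerate: bool = False


def paired_correctness_test(
    correct_a: Sequence[int],
    correct_b: Sequence[int],
    n: int = 50_000,
    seed: int = 0,
) -> PairedTestResult:
    """Paired t-test on two aligned 0/1 correctness vectors.

    ``n`` point indices are sampled without replacement (capped at the
    number available) and the test is run on the paired differences
    ``d_i = a_i - b_i``. Two-sided p-value. Zero-variance differences are
    degenerate: p = 1 when the mean difference is also zero (identical
    performance), p = 0 otherwise (one classifier uniformly better).
    """
    a = np.asarray(correct_a, dtype=np.float64)
    b = np.asarray(correct_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"misaligned correctness vectors: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValidationError("empty correctness vectors")
    n_sampled = min(int(n), a.size)
    rng = np.random.default_rng(seed)
    idx = rng.choice(a.size, size=n_sampled, replace=False)
    d = a[idx] - b[idx]
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if n_sampled > 1 else 0.0
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(n_sampled, 0.0, 0.0, 1.0, seed, degenerate=False)
        t = np.inf if mean > 0 else -np.inf
        return PairedTestResult(n_sampled, mean, float(t), 0.0, seed, degenerate=True)
    t = mean / (sd / np.sqrt(n_sampled))
    p = float(2.0 * stats.t.sf(abs(t), df=n_sampled - 1))
    return PairedTestResult(n_sampled, mean, float(t), p, seed)
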