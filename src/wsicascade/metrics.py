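"""Binary evaluation: confusion matrices, rate metrics, Cohen's kappa, ROC/AUC.

Definitions (standard forms):

    accuracy    = (tp + tn) / n
    sensitivity = tp / (tp + fn)            (recall of the positive class)
    specificity = tn / (tn + fp)
    f1          = 2 tp / (2 tp + fp + fn)
    kappa       = (p_o - p_e) / (1 - p_e),  p_e from the matrix marginals
    AUC         = Mann-Whitney concordance with 0.5 credit for score ties
                  (identical to the trapezoid area under the ROC curve)

A prediction whose confidence does not exceed the vote-confidence threshold
is excluded from the matrix and counted separately as abstained, never
imputed.  Metrics with a zero denominator are reported as NaN and listed in
``MetricsReport.undefined`` rather than silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix2:
    """2x2 confusion matrix with a declared positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str = "positive"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transpose(self) -> "ConfusionMatrix2":
        """Swap the roles of prediction and truth (fp <-> fn)."""
        return ConfusionMatrix2(self.tp, self.fn, self.fp, self.tn, self.positive_class)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    cohen_kappa: float
    auc: float | None
    n_evaluated: int
    n_abstained: int
    level: str = "tile"
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "cohen_kappa": self.cohen_kappa,
            "auc": self.auc,
            "n_evaluated": self.n_evaluated,
            "n_abstained": self.n_abstained,
            "level": self.level,
            "undefined": sorted(self.undefined),
        }


def confusion(
    y_true: Sequence[Hashable],
    y_pred: Sequence[Hashable],
    positive_class: Hashable,
    confidences: Sequence[float] | None = None,
    confidence_threshold: float | None = None,
) -> tuple[ConfusionMatrix2, int]:
    """Tally predictions into a 2x2 matrix, excluding low-confidence votes.

    Returns ``(matrix, n_abstained)``; a vote abstains when its confidence
    is <= ``confidence_threshold``.
    """
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred differ in length")
    if confidence_threshold is not None and confidences is None:
        raise ValidationError("confidence filtering requires per-item confidences")

    classes = set(y_true) | set(y_pred)
    if positive_class not in classes:
        raise ValidationError(f"positive class {positive_class!r} absent from labels")
    if len(classes) > 2:
        raise ValidationError(f"more than two classes present: {sorted(map(str, classes))}")

    tp = fp = fn = tn = abstained = 0
    for i, (t, p) in enumerate(zip(y_true, y_pred)):
        if confidence_threshold is not None and confidences[i] <= confidence_threshold:
            abstained += 1
            continue
        if p == positive_class:
            tp += t == positive_class
            fp += t != positive_class
        else:
            fn += t == positive_class
            tn += t != positive_class
    return ConfusionMatrix2(tp, fp, fn, tn, str(positive_class)), abstained


def _safe_div(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def cohen_kappa(cm: ConfusionMatrix2) -> float:
    """Chance-corrected agreement from the matrix marginals."""
    n = cm.total
    if n == 0:
        return math.nan
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Concordance AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("AUC requires both classes present")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points from a sweep over the unique scores, plus trapezoid AUC.

    ``labels`` are 0/1 with 1 the positive class; scores are positive-class
    probabilities (or any monotone score).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]

    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:  # process tied scores together
            tp += y_sorted[j] == 1
            fp += y_sorted[j] == 0
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j

    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auc)


def compute_metrics(
    cm: ConfusionMatrix2,
    scores: Sequence[float] | None = None,
    labels: Sequence[int] | None = None,
    n_abstained: int = 0,
    level: str = "tile",
) -> MetricsReport:
    """Full metric suite from a confusion matrix (AUC only when scores given)."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix: no confident votes to evaluate")
    undefined: set[str] = set()
    acc = (cm.tp + cm.tn) / cm.total
    sens = _safe_div(cm.tp, cm.tp + cm.fn, "sensitivity", undefined)
    spec = _safe_div(cm.tn, cm.tn + cm.fp, "specificity", undefined)
    f1 = _safe_div(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1", undefined)
    kappa = cohen_kappa(cm)

    auc: float | None = None
    if scores is not None:
        if labels is None:
            raise ValidationError("AUC requires 0/1 labels alongside scores")
        auc = auc_mann_whitney(scores, labels)

    return MetricsReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        cohen_kappa=kappa,
        auc=auc,
        n_evaluated=cm.total,
        n_abstained=n_abstained,
        level=level,
        undefined=frozenset(undefined),
    )
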