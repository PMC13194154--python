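"""Diagnostic-accuracy statistics with Wilson 95% confidence intervals.

Positive class throughout is the high-immunity subtype.  Proportion CIs use
the Wilson score interval; AUC follows the Mann–Whitney formulation (ties
count one half), computed from the trapezoidal ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_curve

from .model import IMMUNITY_H


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion matrix; positive class = high immunity."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with its 95% Wilson interval (all proportions)."""

    value: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV (Wilson CIs) and AUC.

    A metric whose denominator is zero is reported as ``None`` rather than
    NaN-propagated.
    """

    accuracy: MetricEstimate | None
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    auc: float | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            est: MetricEstimate | None = getattr(self, name)
            out[name] = (
                None
                if est is None
                else {"value": est.value, "ci_lower": est.ci_lower, "ci_upper": est.ci_upper}
            )
        out["auc"] = self.auc
        return out


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    For k successes out of n, with z the standard-normal quantile at the
    requested confidence (1.959964 at 95%):

        center = (p + z^2/2n) / (1 + z^2/n)
        half   = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n)

    Bounds are guaranteed inside [0, 1] and always contain p.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = norm.ppf(0.5 + confidence / 2.0)
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n)) / denom
    lower = 0.0 if successes == 0 else max(0.0, center - half)
    upper = 1.0 if successes == n else min(1.0, center + half)
    return (lower, upper)


def confusion_matrix(
    predicted: Sequence[str],
    reference: Sequence[str],
    positive_label: str = IMMUNITY_H,
) -> ConfusionMatrix:
    """Count the 2x2 table; labels must share one two-class vocabulary."""
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference must have equal length")
    vocab = set(predicted) | set(reference)
    if len(vocab) > 2:
        raise ValueError(f"more than two label values present: {sorted(vocab)}")
    tp = fp = fn = tn = 0
    for p, r in zip(predicted, reference):
        if p == positive_label:
            tp += r == positive_label
            fp += r != positive_label
        else:
            fn += r == positive_label
            tn += r != positive_label
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _estimate(successes: int, n: int, confidence: float) -> MetricEstimate | None:
    if n == 0:
        return None
    lo, hi = wilson_ci(successes, n, confidence)
    return MetricEstimate(successes / n, lo, hi)


def classification_metrics(cm: ConfusionMatrix, confidence: float = 0.95) -> MetricsReport:
    """Standard diagnostic-accuracy metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=_estimate(cm.tp + cm.tn, cm.total, confidence),
        sensitivity=_estimate(cm.tp, cm.tp + cm.fn, confidence),
        specificity=_estimate(cm.tn, cm.tn + cm.fp, confidence),
        ppv=_estimate(cm.tp, cm.tp + cm.fp, confidence),
        npv=_estimate(cm.tn, cm.tn + cm.fn, confidence),
    )


def roc_auc(
    scores: Sequence[float],
    reference: Sequence[str],
    positive_label: str = IMMUNITY_H,
) -> tuple[float, np.ndarray]:
    """AUC with ROC points at all unique thresholds.

    The trapezoidal area under the empirical ROC equals the Mann–Whitney
    U-statistic probability P(score_pos > score_neg) + 0.5 P(tie).
    Returns ``(auc, points)`` with points as an (n, 3) array of
    (threshold, fpr, tpr) rows.
    """
    y = np.asarray([lab == positive_label for lab in reference], dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and reference must have equal length")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thresholds = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([thresholds, fpr, tpr])
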