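"""Performance metrics, bootstrap aggregation and model comparison.

All classifier performance in this package is quantified on held-out data with
the metrics below: area under the ROC curve (AUC), accuracy, sensitivity,
specificity, the balanced F-score (F1) and the Matthews correlation
coefficient (MCC).  Per-iteration bootstrap values are aggregated as
mean +/- 1.96 standard errors, and distributions of per-iteration metrics are
compared between models with the two-sided two-sample Kolmogorov-Smirnov test.

The positive class throughout is class 1, the post-treatment period.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

__all__ = [
    "MetricBundle",
    "roc_auc",
    "roc_curve_table",
    "confusion_metrics",
    "aggregate_bootstrap",
    "ks_compare",
]

#: z-quantile used for all 95% confidence intervals.
Z95 = 1.96


@dataclasses.dataclass(frozen=True)
class MetricBundle:
    """Held-out performance of a classifier on one evaluation set.

    ``auc`` may be ``None`` when only hard class predictions are available or
    the evaluation set is single-class.
    """

    auc: float | None
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_f: float
    mcc: float

    def as_dict(self) -> dict[str, float | None]:
        return dataclasses.asdict(self)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2).

    Parameters
    ----------
    scores
        Continuous classifier scores; larger means more class-1-like.
    labels
        Binary labels, class 1 positive.

    Raises
    ------
    ValueError
        If only one class is present in ``labels``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes in `labels`")
    return float(roc_auc_score(labels, scores))


def roc_curve_table(scores: Sequence[float], labels: Sequence[int]):
    """ROC curve as (threshold, tpr, fpr) arrays, for CSV export."""
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return thr, tpr, fpr


def confusion_metrics(predicted: Sequence[int], labels: Sequence[int]) -> MetricBundle:
    """Threshold-based metrics from hard class predictions.

    accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    balanced F = 2TP/(2TP+FP+FN) and
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC
    defined as 0 when any factor in the denominator vanishes.
    """
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and labels must have the same length")
    if predicted.size == 0:
        raise ValueError("empty prediction set")

    tp = int(np.sum((predicted == 1) & (labels == 1)))
    tn = int(np.sum((predicted == 0) & (labels == 0)))
    fp = int(np.sum((predicted == 1) & (labels == 0)))
    fn = int(np.sum((predicted == 0) & (labels == 1)))

    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    balanced_f = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0

    return MetricBundle(
        auc=None,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        balanced_f=balanced_f,
        mcc=mcc,
    )


def aggregate_bootstrap(values: Sequence[float]) -> tuple[float, float, float]:
    """Aggregate per-iteration bootstrap values as mean and 95% CI.

    The CI is mean +/- 1.96 * SE, SE = sd(values, ddof=1)/sqrt(n): the
    standard error of the mean across bootstrap iterations.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("aggregate_bootstrap requires >=2 values")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(values.size))
    return mean, mean - Z95 * se, mean + Z95 * se


def ks_compare(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov comparison of two metric
    distributions (e.g. per-iteration AUCs of two models).

    Uses the exact small-sample null distribution when the combined sample
    size is below 25, the asymptotic one otherwise.  Significance is judged
    at 0.05 by callers.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_compare requires >=2 values in each sample")
    method = "exact" if (a.size + b.size) < 25 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
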