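"""ROC/AUC statistics: rank AUC, normal CIs, and the paired DeLong test.

The DeLong test compares two correlated AUCs measured on the *same* test
set.  It estimates the variances of and covariance between the two AUCs from
per-observation structural components (the midrank placement of each
positive among the negatives and vice versa), then refers
``(AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov)`` to a standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "auc",
    "auc_variance",
    "delong_paired_test",
    "ci_over_loops",
    "ROCComparison",
]


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute an AUC")
    return pos, neg


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _structural_components(scores, labels):
    """Midrank structural components (per-positive V10, per-negative V01)."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    a = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    v10 = (tz[:m] - tx) / n          # placement of each positive
    v01 = 1.0 - (tz[m:] - ty) / m    # placement of each negative
    return a, v10, v01


def auc_variance(scores, labels) -> float:
    """DeLong variance estimate of a single AUC."""
    _, v10, v01 = _structural_components(scores, labels)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


@dataclass(frozen=True)
class ROCComparison:
    """Result of a paired AUC comparison."""

    auc_a: float
    auc_b: float
    z: float
    p: float
    alpha: float = 0.01
    var_a: float = float("nan")
    var_b: float = float("nan")
    cov: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def delong_paired_test(scores_a, scores_b, labels, alpha: float = 0.01) -> ROCComparison:
    """Paired DeLong test for two models' AUCs on the same labels.

    The Z statistic carries the sign of ``auc_a - auc_b``; the p-value is
    two-sided.  Raises when the variance of the difference is degenerate
    (identical structural components), in which case no comparison is
    possible.
    """
    labels = np.asarray(labels, dtype=int)
    if np.array_equal(np.asarray(scores_a, dtype=float), np.asarray(scores_b, dtype=float)):
        a = auc(scores_a, labels)
        v = auc_variance(scores_a, labels)
        return ROCComparison(a, a, 0.0, 1.0, alpha, v, v, v)
    a_a, v10_a, v01_a = _structural_components(scores_a, labels)
    a_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    var_a = np.var(v10_a, ddof=1) / m + np.var(v01_a, ddof=1) / n
    var_b = np.var(v10_b, ddof=1) / m + np.var(v01_b, ddof=1) / n
    cov = (
        np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
        + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    )
    var_diff = var_a + var_b - 2 * cov
    if var_diff <= 0:
        raise ValueError(
            "degenerate DeLong variance (var_a + var_b - 2 cov <= 0): "
            f"var_a={var_a:.3g}, var_b={var_b:.3g}, cov={cov:.3g}; "
            "the paired comparison is not identified on these scores"
        )
    z = (a_a - a_b) / np.sqrt(var_diff)
    p = 2.0 * float(norm.sf(abs(z)))
    return ROCComparison(a_a, a_b, float(z), p, alpha, float(var_a), float(var_b), float(cov))


def ci_over_loops(
    values, clip: tuple[float, float] = (0.0, 100.0)
) -> tuple[float, float, float, float]:
    """Mean, SD, and normal-approximation 95 % CI over outer-loop metrics.

    ``mean +/- 1.96 SD / sqrt(n)``, clipped to the metric's range (percent
    scale by default).  Requires at least two values.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = 1.96 * sd / np.sqrt(len(v))
    lo = max(clip[0], mean - half)
    hi = min(clip[1], mean + half)
    return mean, sd, lo, hi
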