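"""Classical ICC machinery: Swiger asymptotic variance, confidence
intervals, and simple multi-estimate summaries.

The sampling variance of an ANOVA-type ICC estimate from a trial with
``N`` participants in ``k`` clusters (average cluster size ``m = N/k``)
is approximated by the closed form

    V(rho, N, k) = 2 (N - 1) (1 - rho)^2 (1 + (m - 1) rho)^2
                   / (m^2 (N - k) (k - 1))

which requires only (rho, N, k) and vanishes iff rho = 1.  Confidence
intervals are symmetric normal intervals on the raw ICC scale, truncated
to [0, 1].  The multi-estimate summaries (median, mean, weighted mean,
maximum of the pooled estimates) are the conventional comparators to the
Bayesian synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .study_io import StudyTable

__all__ = [
    "IntervalEstimate",
    "ClassicalSummary",
    "swiger_variance",
    "icc_confidence_interval",
    "classical_summaries",
]


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float
    variance: float


@dataclass(frozen=True)
class ClassicalSummary:
    median: float
    mean: float
    weighted_mean: float
    maximum: float


def swiger_variance(rho, n, k):
    """Asymptotic variance of an ICC estimate from n participants in k clusters.

    Accepts scalars or broadcastable arrays; the average cluster size
    n/k is used as a real number.  Requires k >= 2, n > k and rho in
    [0, 1].
    """
    rho_a = np.asarray(rho, dtype=float)
    n_a = np.asarray(n, dtype=float)
    k_a = np.asarray(k, dtype=float)
    if np.any(k_a < 2):
        raise ValueError("number of clusters k must be >= 2")
    if np.any(n_a <= k_a):
        raise ValueError("total participants n must exceed number of clusters k")
    if np.any((rho_a < 0) | (rho_a > 1)):
        raise ValueError("rho must lie in [0, 1]")
    m_bar = n_a / k_a
    num = 2.0 * (n_a - 1.0) * (1.0 - rho_a) ** 2 * (1.0 + (m_bar - 1.0) * rho_a) ** 2
    den = m_bar**2 * (n_a - k_a) * (k_a - 1.0)
    v = num / den
    if np.ndim(rho) == 0 and np.ndim(n) == 0 and np.ndim(k) == 0:
        return float(v)
    return v


def icc_confidence_interval(rho: float, n: int, k: int, level: float = 0.95) -> IntervalEstimate:
    """Normal-approximation interval for an ICC, truncated to [0, 1]."""
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    v = swiger_variance(rho, n, k)
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(v)
    lower = float(np.clip(rho - half, 0.0, 1.0))
    upper = float(np.clip(rho + half, 0.0, 1.0))
    return IntervalEstimate(point=float(rho), lower=lower, upper=upper, level=level, variance=v)


def classical_summaries(table: StudyTable) -> ClassicalSummary:
    """Median, mean, weighted mean and maximum of the pooled ICC estimates.

    All four statistics are computed over the flat list of record-level
    estimates, ignoring study grouping; the weighted mean uses the
    outcome-level relevance weights.
    """
    arrs = table.arrays()
    rho = arrs["icc_hat"]
    if rho.size == 0:
        raise ValueError("cannot summarise an empty study table")
    w = arrs["outcome_weight"]
    return ClassicalSummary(
        median=float(np.median(rho)),
        mean=float(np.mean(rho)),
        weighted_mean=float(np.sum(w * rho) / np.sum(w)),
        maximum=float(np.max(rho)),
    )
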