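"""Design-effect-based power and sample size for two-arm cluster trials.

With k equal-size clusters of m participants per arm and ICC rho, the
clustering inflates the variance of a difference in means by the design
effect DEff = 1 + (m - 1) rho, equivalently shrinks each arm to an
effective size n_eff = k m / DEff.  Two-sided power for detecting a mean
difference delta with common SD sigma is

    power = Phi(ncp - c) + Phi(-ncp - c),   ncp = |delta| / (sigma sqrt(2 / n_eff))

with c the two-sided normal critical value (default), or the central-t
critical value at 2k - 2 (cluster df) or 2km - 2 (subject df) degrees of
freedom for the t variants.

Because n_eff -> k / rho as m grows, power has a ceiling for fixed k and
rho > 0: a target power can be infeasible no matter how large the
clusters are.  ``min_cluster_size`` detects this via the asymptote and
otherwise returns the smallest integer m meeting the target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "design_effect",
    "power_cluster",
    "min_cluster_size",
    "sample_size_over_quantiles",
]

POWER_METHODS = ("normal", "t_cluster_df", "t_subject_df")


@dataclass(frozen=True)
class DesignSpec:
    """Inputs for a two-arm cluster-randomised trial power calculation."""

    delta: float
    sd: float
    icc: float
    k_per_arm: int
    m: int | None = None
    alpha: float = 0.05
    target_power: float = 0.80
    power_method: str = "normal"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.target_power < 1.0):
            raise ValueError("target_power must lie in (0, 1)")
        if not (0.0 <= self.icc <= 1.0):
            raise ValueError("icc must lie in [0, 1]")
        if self.k_per_arm < 2:
            raise ValueError("need at least 2 clusters per arm")
        if self.m is not None and self.m < 1:
            raise ValueError("cluster size m must be >= 1")
        if self.power_method not in POWER_METHODS:
            raise ValueError(f"power_method must be one of {POWER_METHODS}")


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a minimum-cluster-size search."""

    m: int | None
    n_total: int | None
    deff: float | None
    achieved_power: float
    feasible: bool


def design_effect(m: float, rho: float) -> float:
    """Variance inflation 1 + (m - 1) rho for average cluster size m."""
    if m < 1:
        raise ValueError("cluster size m must be >= 1")
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    return 1.0 + (m - 1.0) * rho


def _critical_value(alpha: float, method: str, k: int, m: float) -> float:
    if method == "normal":
        return float(stats.norm.ppf(1.0 - alpha / 2.0))
    if method == "t_cluster_df":
        df = 2 * k - 2
    else:  # t_subject_df
        df = 2.0 * k * m - 2.0
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def _power_at(delta: float, sd: float, alpha: float, n_eff: float, crit: float) -> float:
    ncp = abs(delta) / (sd * np.sqrt(2.0 / n_eff))
    return float(stats.norm.cdf(ncp - crit) + stats.norm.cdf(-ncp - crit))


def power_cluster(spec: DesignSpec) -> float:
    """Two-sided power of the difference-in-means test for ``spec``.

    Requires ``spec.m``; at delta = 0 the value is the type-I rate alpha.
    """
    if spec.m is None:
        raise ValueError("spec.m (cluster size) is required for a power calculation")
    deff = design_effect(spec.m, spec.icc)
    n_eff = spec.k_per_arm * spec.m / deff
    crit = _critical_value(spec.alpha, spec.power_method, spec.k_per_arm, spec.m)
    return _power_at(spec.delta, spec.sd, spec.alpha, n_eff, crit)


def _required_n_eff(delta: float, sd: float, alpha: float, power: float, crit: float) -> float:
    """Per-arm effective size at which the two-sided power reaches target."""
    if delta == 0:
        return np.inf

    def gap(n_eff):
        return _power_at(delta, sd, alpha, n_eff, crit) - power

    hi = 4.0
    while gap(hi) < 0 and hi < 1e12:
        hi *= 4.0
    return float(optimize.brentq(gap, 1e-9, hi, xtol=1e-9))


def min_cluster_size(spec: DesignSpec) -> SampleSizeResult:
    """Smallest integer cluster size m reaching the target power.

    Infeasibility (the k / rho effective-size asymptote sits below the
    requirement) is a result, not an exception: ``feasible`` is False
    and ``achieved_power`` reports the unreachable power ceiling.
    """
    k, rho = spec.k_per_arm, spec.icc
    # Critical value at the m -> inf limit: subject-df t tends to normal.
    limit_method = "t_cluster_df" if spec.power_method == "t_cluster_df" else "normal"
    crit_inf = _critical_value(spec.alpha, limit_method, k, np.inf)
    n_req = _required_n_eff(spec.delta, spec.sd, spec.alpha, spec.target_power, crit_inf)
    if rho > 0:
        p_ceiling = _power_at(spec.delta, spec.sd, spec.alpha, k / rho, crit_inf)
        if k / rho <= n_req:
            return SampleSizeResult(
                m=None, n_total=None, deff=None, achieved_power=p_ceiling, feasible=False
            )
        m = int(np.ceil(n_req * (1.0 - rho) / (k - n_req * rho)))
    else:
        m = int(np.ceil(n_req / k))
    m = max(m, 1)
    # The closed form used the limiting critical value; adjust locally so
    # minimality holds exactly under the configured method.
    while power_cluster(replace(spec, m=m)) < spec.target_power:
        m += 1
        if m > 10**6:
            return SampleSizeResult(
                m=None,
                n_total=None,
                deff=None,
                achieved_power=power_cluster(replace(spec, m=10**6)),
                feasible=False,
            )
    while m > 1 and power_cluster(replace(spec, m=m - 1)) >= spec.target_power:
        m -= 1
    return SampleSizeResult(
        m=m,
        n_total=2 * k * m,
        deff=design_effect(m, rho),
        achieved_power=power_cluster(replace(spec, m=m)),
        feasible=True,
    )


def sample_size_over_quantiles(
    icc_values: Sequence[float] | np.ndarray,
    k_values: Iterable[int],
    base_spec: DesignSpec,
    quantiles: Sequence[float] = (25.0, 50.0, 75.0),
    from_draws: bool = False,
) -> pd.DataFrame:
    """Minimum-cluster-size grid over numbers of clusters and ICC quantiles.

    ``icc_values`` is either the ICC value per requested quantile (in
    order) or, with ``from_draws=True``, raw posterior draws from which
    the quantiles are taken.  Returns one row per (k, quantile) with the
    search result; infeasible cells carry ``feasible=False`` and missing
    m / N.
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("at least one number of clusters required")
    if from_draws:
        iccs = np.percentile(np.asarray(icc_values, dtype=float), list(quantiles))
    else:
        iccs = np.asarray(icc_values, dtype=float)
        if iccs.size != len(quantiles):
            raise ValueError("need one ICC value per requested quantile")
    rows = []
    for k in k_values:
        for q, rho in zip(quantiles, iccs):
            res = min_cluster_size(replace(base_spec, icc=float(rho), k_per_arm=int(k), m=None))
            rows.append(
                {
                    "k_per_arm": int(k),
                    "quantile": float(q),
                    "icc": float(rho),
                    "m": res.m,
                    "n_total": res.n_total,
                    "deff": res.deff,
                    "achieved_power": res.achieved_power,
                    "feasible": res.feasible,
                }
            )
    return pd.DataFrame(rows)
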