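"""Generators with known ground truth for every stage of the pipeline.

Three kinds of synthetic data are produced:

* clustered Gaussian outcomes under a one-way random-effects model with a
  known ICC (cluster effects with variance rho * sigma^2, residuals with
  variance (1 - rho) * sigma^2), together with the standard one-way ANOVA
  ICC estimator;
* study tables drawn forwards from the hierarchical logit-normal model at
  known (mu, sigma_b, sigma_w), either by adding Swiger-variance
  observation noise directly or by simulating a full cluster trial per
  record and estimating its ICC;
* reviewer panels with a controllable level of agreement (a shared
  item-level signal mixed with independent expert noise) and optional
  systematically biased experts.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .classical import swiger_variance
from .study_io import ICCRecord, Study, StudyTable

__all__ = [
    "SimulationTruth",
    "SimulatedTable",
    "simulate_cluster_trial",
    "anova_icc",
    "simulate_study_table",
    "simulate_reviewer_panel",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Generative parameters for the synthetic module.

    ``rho_true``, ``mu_outcome`` and ``sigma_total`` drive single-trial
    simulation; the remaining fields drive study-table generation from
    the hierarchical model (overall logit-ICC mean ``mu``, between-study
    SD ``sigma_b_study``, within-study SD ``sigma_w_study``, and the
    table dimensions).  Source-trial sizes are drawn uniformly from
    ``n_range`` participants and ``k_range`` clusters, spanning the
    scale of published stroke cluster trials.
    """

    rho_true: float = 0.05
    mu_outcome: float = 0.0
    sigma_total: float = 1.0
    mu: float = -3.0
    sigma_b_study: float = 0.5
    sigma_w_study: float = 0.3
    n_studies: int = 30
    outcomes_per_study: int = 3
    n_range: tuple[int, int] = (1000, 5000)
    k_range: tuple[int, int] = (20, 50)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_true < 1.0):
            raise ValueError("rho_true must lie in [0, 1)")
        if self.n_range[0] > self.n_range[1] or self.k_range[0] > self.k_range[1]:
            raise ValueError("empty n_range or k_range")


@dataclass(frozen=True)
class SimulatedTable:
    """A simulated study table plus the latent truth that generated it."""

    table: StudyTable
    mu: float
    sigma_b: float
    sigma_w: float
    mu_m: np.ndarray = field(repr=False)
    rho_ml: np.ndarray = field(repr=False)


def _cluster_sizes(n: int, k: int) -> np.ndarray:
    """Split n participants over k clusters as evenly as possible."""
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    return sizes


def simulate_cluster_trial(
    truth: SimulationTruth,
    n: int,
    k: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate clustered Gaussian outcomes with ICC ``truth.rho_true``.

    Returns a DataFrame with columns ``cluster`` and ``value``; n is
    split over k clusters as evenly as possible.
    """
    if k < 2 or n <= k:
        raise ValueError("need k >= 2 clusters and n > k participants")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    sizes = _cluster_sizes(n, k)
    sigma2 = truth.sigma_total**2
    b = rng.normal(0.0, np.sqrt(truth.rho_true * sigma2), size=k)
    cluster = np.repeat(np.arange(k), sizes)
    e = rng.normal(0.0, np.sqrt((1.0 - truth.rho_true) * sigma2), size=n)
    values = truth.mu_outcome + b[cluster] + e
    return pd.DataFrame({"cluster": cluster, "value": values})


def anova_icc(data: pd.DataFrame) -> float:
    """One-way ANOVA ICC estimate, truncated to [0, 1].

    ICC = (MSB - MSW) / (MSB + (m0 - 1) MSW) with the unbalanced average
    cluster size m0 = (N - sum n_i^2 / N) / (k - 1).  Negative estimates
    are truncated to 0, mirroring how small trials report "0.00".
    """
    groups = data.groupby("cluster")["value"]
    k = groups.ngroups
    if k < 2:
        raise ValueError("at least 2 clusters required")
    sizes = groups.size().to_numpy(dtype=float)
    n_total = sizes.sum()
    means = groups.mean().to_numpy()
    grand = data["value"].mean()
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(((data["value"] - groups.transform("mean")) ** 2).sum())
    msb = ssb / (k - 1)
    if n_total - k <= 0:
        raise ValueError("need more participants than clusters")
    msw = ssw / (n_total - k)
    if msb == 0.0 and msw == 0.0:
        warnings.warn("all outcome values identical; ICC reported as 0", stacklevel=2)
        return 0.0
    m0 = (n_total - np.sum(sizes**2) / n_total) / (k - 1)
    denom = msb + (m0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return float(np.clip((msb - msw) / denom, 0.0, 1.0))


def simulate_study_table(
    truth: SimulationTruth,
    mode: str = "direct",
    rng: np.random.Generator | None = None,
) -> SimulatedTable:
    """Draw a study table forwards from the hierarchical logit-normal model.

    Study means mu_m ~ N(mu, sigma_b^2); record-level logit ICCs
    theta_ml ~ N(mu_m, sigma_w^2); observed estimates either add
    Swiger-variance normal noise around rho_ml (``mode="direct"``) or
    come from a full simulated cluster trial with ICC rho_ml and the
    ANOVA estimator (``mode="trial"``).  Estimates are clipped to [0, 1).
    All relevance weights are 1 (the generative model is the unit-weight
    exchangeable form).
    """
    if mode not in ("direct", "trial"):
        raise ValueError("mode must be 'direct' or 'trial'")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    s, l = truth.n_studies, truth.outcomes_per_study
    mu_m = rng.normal(truth.mu, truth.sigma_b_study, size=s)
    theta = rng.normal(np.repeat(mu_m, l), truth.sigma_w_study)
    rho_ml = expit(theta)
    n = rng.integers(truth.n_range[0], truth.n_range[1] + 1, size=s * l)
    k = rng.integers(truth.k_range[0], truth.k_range[1] + 1, size=s * l)
    k = np.minimum(k, n - 1)  # keep n > k for tiny configured ranges

    if mode == "direct":
        v = swiger_variance(rho_ml, n, k)
        rho_hat = rng.normal(rho_ml, np.sqrt(v))
    else:
        rho_hat = np.empty(s * l)
        for i in range(s * l):
            trial_truth = SimulationTruth(
                rho_true=float(rho_ml[i]),
                mu_outcome=truth.mu_outcome,
                sigma_total=truth.sigma_total,
                seed=truth.seed,
            )
            data = simulate_cluster_trial(trial_truth, int(n[i]), int(k[i]), rng=rng)
            rho_hat[i] = anova_icc(data)
    rho_hat = np.clip(rho_hat, 0.0, np.nextafter(1.0, 0.0))

    studies = []
    for m in range(s):
        recs = tuple(
            ICCRecord(
                study_id=f"S{m + 1}",
                outcome_id=f"S{m + 1}.{j + 1}",
                icc_hat=float(rho_hat[m * l + j]),
                n_participants=int(n[m * l + j]),
                n_clusters=int(k[m * l + j]),
            )
            for j in range(l)
        )
        studies.append(Study(study_id=f"S{m + 1}", records=recs))
    table = StudyTable(tuple(studies))
    table.validate()
    return SimulatedTable(
        table=table,
        mu=truth.mu,
        sigma_b=truth.sigma_b_study,
        sigma_w=truth.sigma_w_study,
        mu_m=mu_m,
        rho_ml=rho_ml,
    )


def simulate_reviewer_panel(
    n_experts: int,
    n_items: int,
    agreement: float,
    seed: int = 0,
    n_biased: int = 0,
    bias: float = 0.3,
) -> pd.DataFrame:
    """Simulate an expert ratings matrix with controllable agreement.

    Each rating is ``agreement * s_i + (1 - agreement) * e_ji`` where
    ``s_i`` is a shared uniform item signal and ``e_ji`` independent
    uniform expert noise, so expected inter-rater correlation rises from
    0 (agreement=0) to 1 (agreement=1).  The last ``n_biased`` experts
    have ``bias`` subtracted from their ratings (clipped to [0, 1]),
    emulating systematically deviant raters a reliability analysis
    should flag.
    """
    if not (0.0 <= agreement <= 1.0):
        raise ValueError("agreement must lie in [0, 1]")
    if n_biased > n_experts:
        raise ValueError("n_biased cannot exceed n_experts")
    rng = np.random.default_rng(seed)
    signal = rng.uniform(size=n_items)
    noise = rng.uniform(size=(n_experts, n_items))
    ratings = agreement * signal[None, :] + (1.0 - agreement) * noise
    if n_biased:
        ratings[-n_biased:, :] = np.clip(ratings[-n_biased:, :] - bias, 0.0, 1.0)
    return pd.DataFrame(
        ratings,
        index=[f"R{j + 1}" for j in range(n_experts)],
        columns=[f"item{i + 1}" for i in range(n_items)],
    )
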