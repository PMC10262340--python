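"""Aggregation of expert relevance ratings into pooled weights.

A panel of J experts rates the relevance of each study (and each outcome)
to the planned trial on [0, 1].  Ratings are held as a pandas DataFrame
with one row per expert and one column per rated item; missing entries
(NaN) are allowed and handled per item.

Per-expert *importance weights* come from the Rank-Sum rule: expert j
with rank Rank_j (1 = best) receives

    pi_j = (J - Rank_j + 1) / sum_i (J - Rank_i + 1)

so weights sum to one and better-ranked experts count for more.  Pooled
item weights are the linear opinion pool sum_j pi_j * rating_{j,item},
renormalising pi over the experts who actually rated an item.

Reliability diagnostics (Cronbach's alpha treating experts as items and
rated studies as cases, the inter-rater correlation matrix, and per-item
five-number spread summaries) support a human judgement about whether any
expert should be down-ranked before pooling; the package never
down-ranks automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceWeights",
    "rank_sum_weights",
    "pool_opinions",
    "cronbach_alpha",
    "interrater_correlations",
]

#: Floor applied to pooled weights before they enter the hierarchical
#: model, whose variances are divided by the weights.
WEIGHT_FLOOR = 0.01


@dataclass(frozen=True)
class ImportanceWeights:
    """Per-expert pooling weights and the ranks that produced them."""

    pi: tuple[float, ...]
    ranks: tuple[int, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.pi) - 1.0) > 1e-12:
            raise ValueError("importance weights must sum to 1")
        if any(p < 0 for p in self.pi):
            raise ValueError("importance weights must be nonnegative")


def rank_sum_weights(ranks) -> ImportanceWeights:
    """Rank-Sum importance weights from per-expert ranks (1 = best).

    Ties are allowed; equal ranks give equal weights.
    """
    ranks = [int(r) for r in ranks]
    j = len(ranks)
    if j < 1:
        raise ValueError("at least one expert required")
    if any(r < 1 or r > j for r in ranks):
        raise ValueError(f"ranks must lie in 1..{j}, got {ranks}")
    scores = np.array([j - r + 1 for r in ranks], dtype=float)
    pi = scores / scores.sum()
    return ImportanceWeights(pi=tuple(pi.tolist()), ranks=tuple(ranks))


def _as_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(ratings).astype(float)
    vals = df.to_numpy()
    present = ~np.isnan(vals)
    if np.any((vals[present] < 0) | (vals[present] > 1)):
        raise ValueError("ratings must lie in [0, 1]")
    return df


def pool_opinions(
    ratings: pd.DataFrame,
    weights: ImportanceWeights,
    floor: float | None = WEIGHT_FLOOR,
) -> pd.Series:
    """Linear opinion pool of expert ratings, one pooled weight per item.

    ``ratings`` has experts as rows and items as columns.  Importance
    weights are renormalised over the experts who rated each item.  A
    pooled weight below ``floor`` is raised to it (with a warning), since
    downstream model variances are divided by the weight; pass
    ``floor=None`` to disable.
    """
    df = _as_ratings(ratings)
    if len(df) != len(weights.pi):
        raise ValueError(
            f"ratings have {len(df)} experts but {len(weights.pi)} importance weights"
        )
    pi = np.asarray(weights.pi, dtype=float)
    pooled = {}
    for item in df.columns:
        col = df[item].to_numpy()
        mask = ~np.isnan(col)
        if not mask.any():
            raise ValueError(f"item {item!r} was rated by no expert")
        pj = pi[mask]
        if pj.sum() == 0:
            raise ValueError(f"item {item!r} rated only by zero-weight experts")
        pooled[item] = float(np.sum(pj * col[mask]) / pj.sum())
    out = pd.Series(pooled, name="pooled_weight")[df.columns]
    if floor is not None:
        low = out < floor
        if low.any():
            warnings.warn(
                f"{int(low.sum())} pooled weight(s) below {floor} floored to keep "
                "model variances finite",
                stacklevel=2,
            )
            out = out.clip(lower=floor)
    return out


def cronbach_alpha(ratings: pd.DataFrame) -> float:
    """Cronbach's alpha over the panel: experts as items, studies as cases.

    alpha = J/(J-1) * (1 - sum_j var_j / var_total), with var_total the
    variance of the per-case rating sums.  Incomplete rows are dropped
    with a warning; zero total variance is signalled as an error.
    """
    df = _as_ratings(ratings)
    j = len(df)
    if j < 2:
        raise ValueError("Cronbach's alpha needs at least 2 experts")
    cases = df.T  # rows = rated items (cases), columns = experts
    if cases.isna().any().any():
        warnings.warn("dropping items with missing ratings for alpha", stacklevel=2)
        cases = cases.dropna(axis=0)
    if len(cases) < 2:
        raise ValueError("Cronbach's alpha needs at least 2 complete items")
    var_j = cases.var(axis=0, ddof=1)
    var_total = cases.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("total variance is zero; alpha undefined for constant ratings")
    return float(j / (j - 1) * (1.0 - var_j.sum() / var_total))


def interrater_correlations(
    ratings: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise expert correlation matrix and per-item spread summaries.

    Returns ``(corr, spread)`` where ``corr`` is the J x J Pearson
    correlation matrix between experts (unit diagonal; NaN, with a
    warning, for any constant rater) and ``spread`` holds the per-item
    five-number summary (min, q1, median, q3, max) of the panel ratings.
    """
    df = _as_ratings(ratings)
    cases = df.T  # items as rows, experts as columns
    sd = cases.std(ddof=1)
    if (sd == 0).any():
        constant = list(sd.index[sd == 0])
        warnings.warn(
            f"constant rater(s) {constant}: correlations reported as missing",
            stacklevel=2,
        )
    corr = cases.corr()
    np.fill_diagonal(corr.values, 1.0)
    spread = pd.DataFrame(
        {
            "min": cases.min(axis=1),
            "q1": cases.quantile(0.25, axis=1),
            "median": cases.median(axis=1),
            "q3": cases.quantile(0.75, axis=1),
            "max": cases.max(axis=1),
        }
    )
    return corr, spread
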