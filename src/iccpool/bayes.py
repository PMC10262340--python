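"""Weighted Bayesian hierarchical logit-normal model for ICC synthesis.

Model, for outcome l of study m with estimate rho_hat_ml from a trial of
N_ml participants in k_ml clusters, and relevance weights w_ml (outcome)
and w_m (study):

    rho_hat_ml ~ N(rho_ml, V(rho_ml, N_ml, k_ml))
    logit(rho_ml) ~ N(mu_m, sigma_w^2 / w_ml)
    mu_m ~ N(mu, sigma_b^2 / w_m)
    mu ~ N(0, 10 000),   sigma_w, sigma_b ~ U[0, 5]

where V is the Swiger asymptotic variance.  Down-weighting an estimate
(w < 1) inflates the variance of its level of the hierarchy, so less
relevant estimates borrow less strength.  The likelihood acts on the raw
estimate scale, so rho_hat = 0 records are legal; only the latent
rho_ml lives in (0, 1) via the logit link.

The sampler is Metropolis-within-Gibbs: exact conjugate Gibbs updates
for mu and the mu_m given the latent logit ICCs, slice sampling for
sigma_b and sigma_w on their bounded (0, upper] supports, and a
random-walk Metropolis step on each logit(rho_ml) (non-conjugate because
V depends on rho_ml), adapted during burn-in only.  A joint translation
move shifting mu, every mu_m and every logit(rho_ml) by a common offset
(accepted against the mu prior and the observation likelihood alone,
since the within-hierarchy terms depend only on differences) lets the
chain traverse the very wide mu prior quickly when the data are weak.  Each retained
iteration also records a posterior *predictive* ICC draw for a new,
fully relevant study and outcome:

    rho_star = expit(x),  x ~ N(mu_star, sigma_w^2),  mu_star ~ N(mu, sigma_b^2)

which is the "target ICC" whose posterior summaries feed the sample-size
calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .classical import swiger_variance
from .study_io import StudyTable

__all__ = [
    "ModelConfig",
    "ModelState",
    "PosteriorDraws",
    "PosteriorSummary",
    "log_posterior",
    "fit_model",
    "summary_stats",
    "summarize_posterior",
    "convergence_diagnostics",
    "dic",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelConfig:
    """Priors, MCMC settings and variance conventions.

    ``variance_at`` selects where the Swiger variance is evaluated:
    ``"latent"`` (the model as written, V a function of the latent
    rho_ml) or ``"observed"`` (V fixed at the reported estimate).
    ``variance_inflation`` multiplies every observation variance; values
    much greater than 1 make the data nearly uninformative, which is
    useful for prior-recovery checks.
    """

    prior_mu_mean: float = 0.0
    prior_mu_var: float = 10_000.0
    prior_sigma_upper: float = 5.0
    n_chains: int = 4
    n_iter: int = 30_000
    n_burnin: int = 10_000
    thin: int = 1
    seed: int = 0
    variance_at: str = "latent"
    proposal_scale: float = 0.5
    variance_inflation: float = 1.0

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_mu_var <= 0 or self.prior_sigma_upper <= 0:
            raise ValueError("prior scales must be positive")
        if self.variance_at not in ("latent", "observed"):
            raise ValueError("variance_at must be 'latent' or 'observed'")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.proposal_scale <= 0 or self.variance_inflation <= 0:
            raise ValueError("proposal_scale and variance_inflation must be positive")


@dataclass(frozen=True)
class ModelState:
    """A full parameter vector: hyperparameters, study means, latent ICCs."""

    mu: float
    sigma_b: float
    sigma_w: float
    mu_m: np.ndarray
    rho_ml: np.ndarray


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (chains, draws[, dimension])."""

    mu: np.ndarray
    sigma_b: np.ndarray
    sigma_w: np.ndarray
    mu_m: np.ndarray
    rho_ml: np.ndarray
    rho_star: np.ndarray
    study_ids: tuple[str, ...]
    record_ids: tuple[tuple[str, str], ...]
    acceptance: np.ndarray
    config: ModelConfig

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Chain-pooled draws of a monitored quantity ('icc' = rho_star)."""
        arr = getattr(self, "rho_star" if name == "icc" else name)
        return arr.reshape(-1, *arr.shape[2:])


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    mc_error: float
    percentiles: dict[float, float]


def _normal_logpdf(x, mean, var):
    return -0.5 * (_LOG2PI + np.log(var)) - (x - mean) ** 2 / (2.0 * var)


def _obs_loglik(rho_hat, rho, n, k, config: ModelConfig, v_obs=None):
    """Observation log-density N(rho_hat; rho, V * inflation), elementwise.

    V evaluated at the latent rho or held fixed at the observed estimate
    depending on the config; V = 0 (rho at 1) yields -inf.
    """
    if config.variance_at == "observed":
        v = v_obs
    else:
        v = swiger_variance(rho, n, k) * config.variance_inflation
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = _normal_logpdf(rho_hat, rho, v)
    return np.where(v > 0, lp, -np.inf)


def log_posterior(state: ModelState, table: StudyTable, config: ModelConfig) -> float:
    """Log joint density of the full parameter vector (latent ICCs on the
    logit scale) given the study table.  Returns -inf outside the support.
    """
    arrs = table.arrays()
    rho_ml = np.asarray(state.rho_ml, dtype=float)
    mu_m = np.asarray(state.mu_m, dtype=float)
    if mu_m.shape != arrs["study_weight"].shape or rho_ml.shape != arrs["icc_hat"].shape:
        raise ValueError("state dimensions do not match the study table")
    upper = config.prior_sigma_upper
    if not (0.0 < state.sigma_b <= upper) or not (0.0 < state.sigma_w <= upper):
        return -np.inf
    if np.any((rho_ml <= 0.0) | (rho_ml >= 1.0)):
        return -np.inf
    theta = logit(rho_ml)
    v_obs = None
    if config.variance_at == "observed":
        v_obs = swiger_variance(arrs["icc_hat"], arrs["n"], arrs["k"]) * config.variance_inflation
    lp = float(
        np.sum(_obs_loglik(arrs["icc_hat"], rho_ml, arrs["n"], arrs["k"], config, v_obs))
    )
    lp += float(
        np.sum(
            _normal_logpdf(
                theta,
                mu_m[arrs["study_index"]],
                state.sigma_w**2 / arrs["outcome_weight"],
            )
        )
    )
    lp += float(
        np.sum(_normal_logpdf(mu_m, state.mu, state.sigma_b**2 / arrs["study_weight"]))
    )
    lp += float(_normal_logpdf(state.mu, config.prior_mu_mean, config.prior_mu_var))
    lp += -2.0 * np.log(upper)  # two uniform SD priors
    return lp


def _slice_bounded(logf, x0: float, upper: float, rng: np.random.Generator) -> float:
    """Slice-sample a scalar with support (0, upper] by shrinkage from the
    full interval.  ``logf`` is the unnormalised log conditional.
    """
    ly = logf(x0) + np.log(rng.uniform())
    lo, hi = 0.0, upper
    for _ in range(500):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= ly:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # shrinkage exhausted; keep current value


def _run_chain(arrs, config: ModelConfig, rng: np.random.Generator):
    rho_hat = arrs["icc_hat"]
    n, k = arrs["n"], arrs["k"]
    w_l = arrs["outcome_weight"]
    w_s = arrs["study_weight"]
    sidx = arrs["study_index"]
    n_rec, n_stud = rho_hat.size, w_s.size
    upper = config.prior_sigma_upper

    v_obs = None
    if config.variance_at == "observed":
        v_obs = swiger_variance(rho_hat, n, k) * config.variance_inflation

    # Initialise near the data, jittered per chain.
    theta = logit(np.clip(rho_hat, 5e-3, 0.95)) + 0.1 * rng.standard_normal(n_rec)
    mu_m = np.bincount(sidx, weights=w_l * theta, minlength=n_stud) / np.bincount(
        sidx, weights=w_l, minlength=n_stud
    )
    mu = float(np.mean(mu_m))
    sigma_b = min(1.0, 0.5 * upper)
    sigma_w = min(0.5, 0.5 * upper)
    scales = np.full(n_rec, config.proposal_scale)
    shift_scale = 1.0
    shift_acc = 0

    kept = (config.n_iter - config.n_burnin) // config.thin
    out = {
        "mu": np.empty(kept),
        "sigma_b": np.empty(kept),
        "sigma_w": np.empty(kept),
        "mu_m": np.empty((kept, n_stud)),
        "rho_ml": np.empty((kept, n_rec)),
        "rho_star": np.empty(kept),
    }
    acc_total = np.zeros(n_rec)
    acc_window = np.zeros(n_rec)
    n_after = 0
    j = 0

    lp_obs = _obs_loglik(rho_hat, expit(theta), n, k, config, v_obs)
    for t in range(config.n_iter):
        sw2, sb2 = sigma_w**2, sigma_b**2
        # mu | mu_m, sigma_b  (conjugate normal)
        prec = 1.0 / config.prior_mu_var + w_s.sum() / sb2
        mean = (config.prior_mu_mean / config.prior_mu_var + (w_s @ mu_m) / sb2) / prec
        mu = mean + rng.standard_normal() / np.sqrt(prec)
        # mu_m | theta, mu, sigmas  (conjugate normal, vectorised over studies)
        grp_w = np.bincount(sidx, weights=w_l, minlength=n_stud)
        grp_wt = np.bincount(sidx, weights=w_l * theta, minlength=n_stud)
        prec_m = w_s / sb2 + grp_w / sw2
        mean_m = (mu * w_s / sb2 + grp_wt / sw2) / prec_m
        mu_m = mean_m + rng.standard_normal(n_stud) / np.sqrt(prec_m)
        # sigma_b, sigma_w | rest  (slice within (0, upper])
        ss_b = float(np.sum(w_s * (mu_m - mu) ** 2))
        sigma_b = _slice_bounded(
            lambda s: -n_stud * np.log(s) - ss_b / (2.0 * s * s), sigma_b, upper, rng
        )
        ss_w = float(np.sum(w_l * (theta - mu_m[sidx]) ** 2))
        sigma_w = _slice_bounded(
            lambda s: -n_rec * np.log(s) - ss_w / (2.0 * s * s), sigma_w, upper, rng
        )
        sw2 = sigma_w**2
        # theta | rest  (random-walk Metropolis, vectorised over records)
        prop = theta + scales * rng.standard_normal(n_rec)
        lp_obs = _obs_loglik(rho_hat, expit(theta), n, k, config, v_obs)
        lp_prop = _obs_loglik(rho_hat, expit(prop), n, k, config, v_obs)
        delta = (
            lp_prop
            - lp_obs
            - w_l * ((prop - mu_m[sidx]) ** 2 - (theta - mu_m[sidx]) ** 2) / (2.0 * sw2)
        )
        accept = np.log(rng.uniform(size=n_rec)) < delta
        theta = np.where(accept, prop, theta)
        acc_window += accept
        # joint translation of (mu, mu_m, theta): within-hierarchy terms
        # cancel, so only the mu prior and observation likelihood decide
        shift = shift_scale * rng.standard_normal()
        lp_cur = float(np.sum(np.where(accept, lp_prop, lp_obs)))
        lp_new = float(np.sum(_obs_loglik(rho_hat, expit(theta + shift), n, k, config, v_obs)))
        d_prior = (
            (mu - config.prior_mu_mean) ** 2 - (mu + shift - config.prior_mu_mean) ** 2
        ) / (2.0 * config.prior_mu_var)
        if np.log(rng.uniform()) < lp_new - lp_cur + d_prior:
            mu += shift
            mu_m = mu_m + shift
            theta = theta + shift
            shift_acc += 1
        if t >= config.n_burnin:
            acc_total += accept
            n_after += 1
        # adapt proposal scales during burn-in only, targeting 0.2-0.5
        if t < config.n_burnin and (t + 1) % 100 == 0:
            rate = acc_window / 100.0
            scales = scales * np.where(rate < 0.2, 0.7, np.where(rate > 0.5, 1.4, 1.0))
            acc_window[:] = 0.0
            srate = shift_acc / 100.0
            shift_scale *= 0.7 if srate < 0.2 else (1.4 if srate > 0.5 else 1.0)
            shift_acc = 0
        elif (t + 1) % 100 == 0:
            acc_window[:] = 0.0
            shift_acc = 0

        if not (np.isfinite(mu) and np.isfinite(sigma_b) and np.isfinite(sigma_w)):
            raise RuntimeError(f"chain diverged (non-finite state) at iteration {t}")

        if t >= config.n_burnin and (t - config.n_burnin) % config.thin == 0:
            # posterior predictive ICC for a new unit-weight study/outcome
            mu_star = mu + sigma_b * rng.standard_normal()
            x = mu_star + sigma_w * rng.standard_normal()
            tiny = np.finfo(float).tiny
            out["mu"][j] = mu
            out["sigma_b"][j] = sigma_b
            out["sigma_w"][j] = sigma_w
            out["mu_m"][j] = mu_m
            out["rho_ml"][j] = np.clip(expit(theta), tiny, np.nextafter(1.0, 0.0))
            out["rho_star"][j] = float(
                np.clip(expit(x), tiny, np.nextafter(1.0, 0.0))
            )
            j += 1
    return out, acc_total / max(n_after, 1)


def fit_model(table: StudyTable, config: ModelConfig) -> PosteriorDraws:
    """Fit the hierarchical model by Metropolis-within-Gibbs MCMC.

    Fully reproducible given ``config.seed``; chains get independent
    streams spawned from it.
    """
    table.validate()
    arrs = table.arrays()
    if np.any(arrs["outcome_weight"] <= 0) or np.any(arrs["study_weight"] <= 0):
        raise ValueError("all relevance weights must be positive")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    acc = []
    for ss in seeds:
        out, a = _run_chain(arrs, config, np.random.default_rng(ss))
        chains.append(out)
        acc.append(a)
    return PosteriorDraws(
        mu=np.stack([c["mu"] for c in chains]),
        sigma_b=np.stack([c["sigma_b"] for c in chains]),
        sigma_w=np.stack([c["sigma_w"] for c in chains]),
        mu_m=np.stack([c["mu_m"] for c in chains]),
        rho_ml=np.stack([c["rho_ml"] for c in chains]),
        rho_star=np.stack([c["rho_star"] for c in chains]),
        study_ids=tuple(s.study_id for s in table.studies),
        record_ids=tuple((r.study_id, r.outcome_id) for r in table.records),
        acceptance=np.stack(acc),
        config=config,
    )


def summary_stats(x: np.ndarray) -> PosteriorSummary:
    """Mean, SD, batch-means MC error and standard percentiles of draws."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws to summarise, got {n}")
    n_batch = int(np.sqrt(n))
    batch_size = n // n_batch
    means = x[: n_batch * batch_size].reshape(n_batch, batch_size).mean(axis=1)
    mc = float(np.std(means, ddof=1) / np.sqrt(n_batch))
    qs = (2.5, 25.0, 50.0, 75.0, 97.5)
    pct = dict(zip(qs, np.percentile(x, qs).tolist()))
    return PosteriorSummary(
        mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), mc_error=mc, percentiles=pct
    )


MONITORED = ("icc", "mu", "sigma_b", "sigma_w")


def summarize_posterior(
    draws: PosteriorDraws, quantities: tuple[str, ...] = MONITORED
) -> dict[str, PosteriorSummary]:
    """Posterior summaries per monitored quantity ('icc' is the
    predictive ICC rho_star)."""
    return {q: summary_stats(draws.stacked(q)) for q in quantities}


def _split_rhat(chains: np.ndarray) -> float:
    """Potential scale reduction factor on split chains, floored at 1.

    Zero variance everywhere (all chains constant and equal) gives 1;
    separated constant chains give inf.
    """
    c, t = chains.shape
    half = t // 2
    if half < 2:
        raise ValueError("chains too short to split")
    sub = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    w = float(np.mean(np.var(sub, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(sub, axis=1), ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else float("inf")
    nn = sub.shape[1]
    var_plus = (nn - 1) / nn * w + b_over_n
    return max(1.0, float(np.sqrt(var_plus / w)))


def convergence_diagnostics(draws: PosteriorDraws, rhat_limit: float = 1.05):
    """Split-Rhat and effective sample size per monitored quantity.

    Returns a DataFrame indexed by quantity with columns ``rhat`` and
    ``ess``, plus a ``converged`` flag in ``DataFrame.attrs`` set to
    False if any Rhat exceeds ``rhat_limit``.
    """
    import arviz as az
    import pandas as pd

    arr = {q: getattr(draws, "rho_star" if q == "icc" else q) for q in MONITORED}
    c, t = draws.mu.shape
    if c < 2 and t < 200:
        raise ValueError("need >= 2 chains or >= 200 draws for split-chain diagnostics")
    rows = {}
    for q, a in arr.items():
        if c < 2:  # split the single chain in two for both diagnostics
            a = a.reshape(2, t // 2)
        rhat = _split_rhat(a)
        ess = float(az.ess(np.ascontiguousarray(a)))
        rows[q] = {"rhat": rhat, "ess": ess}
    df = pd.DataFrame(rows).T
    df.attrs["converged"] = bool((df["rhat"] <= rhat_limit).all())
    return df


def dic(
    draws: PosteriorDraws,
    table: StudyTable,
    config: ModelConfig | None = None,
    max_draws: int = 10_000,
) -> dict[str, float]:
    """Deviance information criterion DIC = mean deviance + p_D.

    Deviance is -2 times the observation-level log likelihood; the
    effective parameter count p_D is the mean deviance minus the
    deviance at the posterior mean of the latent ICCs.  Used to compare
    fits across sensitivity scenarios (e.g. all studies vs the most
    relevant subset).
    """
    config = draws.config if config is None else config
    arrs = table.arrays()
    rho = draws.stacked("rho_ml")
    if rho.shape[1] != arrs["icc_hat"].size:
        raise ValueError("draw dimension does not match table record count")
    if rho.shape[0] > max_draws:
        idx = np.linspace(0, rho.shape[0] - 1, max_draws).astype(int)
        rho = rho[idx]
    v_obs = None
    if config.variance_at == "observed":
        v_obs = swiger_variance(arrs["icc_hat"], arrs["n"], arrs["k"]) * config.variance_inflation

    def deviance(r):
        ll = _obs_loglik(arrs["icc_hat"], r, arrs["n"], arrs["k"], config, v_obs)
        return -2.0 * np.sum(ll, axis=-1)

    d_bar = float(np.mean(deviance(rho)))
    d_hat = float(deviance(rho.mean(axis=0)))
    p_d = d_bar - d_hat
    return {"dic": d_bar + p_d, "mean_deviance": d_bar, "p_d": p_d}
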