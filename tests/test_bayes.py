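"""Hierarchical model: log-posterior oracle, sampler behaviour, summaries,
diagnostics and DIC."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from iccpool.bayes import (
    ModelConfig,
    ModelState,
    PosteriorDraws,
    convergence_diagnostics,
    dic,
    fit_model,
    log_posterior,
    summarize_posterior,
    summary_stats,
)
from iccpool.synthetic import SimulationTruth, simulate_study_table

from .conftest import make_table


def _single_record_table(icc=0.1, n=100, k=10, w=1.0):
    return make_table([("A", "A.1", icc, n, k, w)])


def _swiger(rho, n, k):
    # independent re-derivation for the oracle below
    m = n / k
    return 2 * (n - 1) * (1 - rho) ** 2 * (1 + (m - 1) * rho) ** 2 / (m**2 * (n - k) * (k - 1))


class TestLogPosterior:
    def test_term_by_term_oracle(self):
        table = _single_record_table()
        config = ModelConfig()
        rho = 0.1
        theta = logit(rho)
        state = ModelState(
            mu=theta, sigma_b=1.0, sigma_w=0.5, mu_m=np.array([theta]), rho_ml=np.array([rho])
        )
        expected = (
            stats.norm.logpdf(0.1, rho, np.sqrt(_swiger(rho, 100, 10)))
            + stats.norm.logpdf(theta, theta, 0.5)
            + stats.norm.logpdf(theta, theta, 1.0)
            + stats.norm.logpdf(theta, 0.0, 100.0)
            + 2 * np.log(1 / 5)
        )
        assert log_posterior(state, table, config) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize(
        "patch",
        [
            {"sigma_b": 5.5},
            {"sigma_w": -0.1},
            {"rho_ml": np.array([0.0])},
            {"rho_ml": np.array([1.0])},
        ],
    )
    def test_outside_support_is_minus_inf(self, patch):
        table = _single_record_table()
        base = dict(
            mu=0.0, sigma_b=1.0, sigma_w=0.5, mu_m=np.array([0.0]), rho_ml=np.array([0.1])
        )
        base.update(patch)
        assert log_posterior(ModelState(**base), table, ModelConfig()) == -np.inf

    def test_weight_doubling_closed_form(self):
        # doubling an outcome weight from 0.5 to 1.0 changes only the
        # second-level term: delta = 0.5 log 2 - (theta - mu_m)^2 * dw / (2 sw^2)
        theta, mu_m, sw = logit(0.08), -2.0, 0.5
        state = ModelState(
            mu=-2.0, sigma_b=1.0, sigma_w=sw, mu_m=np.array([mu_m]), rho_ml=np.array([0.08])
        )
        lp_half = log_posterior(state, _single_record_table(w=0.5), ModelConfig())
        lp_full = log_posterior(state, _single_record_table(w=1.0), ModelConfig())
        expected = 0.5 * np.log(2.0) - (theta - mu_m) ** 2 * 0.5 / (2 * sw**2)
        assert lp_full - lp_half == pytest.approx(expected, abs=1e-10)


class TestFitModel:
    CFG = ModelConfig(n_chains=2, n_iter=3000, n_burnin=1000, seed=42)

    def test_seed_determinism(self, table1):
        d1 = fit_model(table1, self.CFG)
        d2 = fit_model(table1, self.CFG)
        for name in ("mu", "sigma_b", "sigma_w", "rho_star", "rho_ml"):
            assert np.array_equal(getattr(d1, name), getattr(d2, name))

    def test_rho_star_in_unit_interval_and_monotone_percentiles(self, table1):
        d = fit_model(table1, self.CFG)
        x = d.stacked("icc")
        assert np.all((x > 0) & (x < 1))
        s = summary_stats(x)
        qs = [s.percentiles[p] for p in (2.5, 25.0, 50.0, 75.0, 97.5)]
        assert qs == sorted(qs)
        assert np.all(d.stacked("sigma_b") <= d.config.prior_sigma_upper)

    def test_nonpositive_weight_rejected(self):
        from iccpool.study_io import ICCRecord, Study, StudyTable

        rec = ICCRecord("A", "A.1", 0.1, 100, 10, outcome_weight=0.0)
        t = StudyTable((Study("A", 1.0, (rec,)),))
        with pytest.raises(ValueError):
            fit_model(t, self.CFG)

    def test_parameter_recovery_single_table(self):
        # one replicate: tolerances combine posterior SD with the
        # finite-sample spread of the realised hierarchy (30 studies,
        # 90 records); the multi-replicate coverage check lives in the
        # acceptance suite
        truth = SimulationTruth(seed=7)
        sim = simulate_study_table(truth)
        d = fit_model(sim.table, ModelConfig(n_chains=1, n_iter=6000, n_burnin=2000, seed=2))
        s = summarize_posterior(d, ("mu", "sigma_b", "sigma_w"))
        s_stud, n_rec = truth.n_studies, truth.n_studies * truth.outcomes_per_study
        realization_sd = {
            "mu": truth.sigma_b_study / np.sqrt(s_stud),
            "sigma_b": truth.sigma_b_study / np.sqrt(2 * s_stud),
            "sigma_w": truth.sigma_w_study / np.sqrt(2 * n_rec),
        }
        for q, true in (
            ("mu", truth.mu),
            ("sigma_b", truth.sigma_b_study),
            ("sigma_w", truth.sigma_w_study),
        ):
            tol = 3 * np.hypot(s[q].sd, realization_sd[q])
            assert abs(s[q].percentiles[50.0] - true) < tol

    def test_symmetric_records_exchangeable(self):
        # with unit weights the posterior must not depend on record order
        t_a = make_table([("A", "A.1", 0.02, 500, 20, 1.0), ("B", "B.1", 0.2, 500, 20, 1.0)])
        t_b = make_table([("A", "A.1", 0.2, 500, 20, 1.0), ("B", "B.1", 0.02, 500, 20, 1.0)])
        cfg = ModelConfig(n_chains=2, n_iter=8000, n_burnin=2000, seed=3)
        s_a = summarize_posterior(fit_model(t_a, cfg), ("mu",))["mu"]
        s_b = summarize_posterior(fit_model(t_b, cfg), ("mu",))["mu"]
        tol = 4 * np.hypot(s_a.mc_error, s_b.mc_error)
        assert abs(s_a.mean - s_b.mean) < tol

    def test_weight_pulls_posterior_toward_heavier_record(self):
        # two well-separated estimates; upweighting one must move the
        # predictive ICC median toward it
        recs = [("A", "A.1", 0.02, 2000, 40, 1.0), ("A", "A.2", 0.3, 2000, 40, 1.0)]
        cfg = ModelConfig(n_chains=2, n_iter=8000, n_burnin=2000, seed=4)
        base = summarize_posterior(fit_model(make_table(recs), cfg), ("icc",))["icc"]
        up_low = [("A", "A.1", 0.02, 2000, 40, 1.0), ("A", "A.2", 0.3, 2000, 40, 0.05)]
        shifted = summarize_posterior(fit_model(make_table(up_low), cfg), ("icc",))["icc"]
        # down-weighting the larger estimate pulls the median down
        assert shifted.percentiles[50.0] < base.percentiles[50.0]


class TestSummaries:
    def test_constant_draws(self):
        s = summary_stats(np.full(500, 0.3))
        assert s.mean == pytest.approx(0.3, abs=1e-15)
        assert s.sd == pytest.approx(0.0, abs=1e-15)
        assert s.mc_error == pytest.approx(0.0, abs=1e-15)
        assert all(v == 0.3 for v in s.percentiles.values())

    def test_uniform_grid_percentiles(self):
        x = np.arange(1, 10_001) / 10_001.0
        s = summary_stats(x)
        assert s.percentiles[2.5] == pytest.approx(0.025, abs=1e-3)
        assert s.percentiles[50.0] == pytest.approx(0.5, abs=1e-3)
        assert s.mean == pytest.approx(0.5, abs=1e-4)

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="100"):
            summary_stats(np.ones(50))

    def test_mc_error_below_sd(self, rng):
        s = summary_stats(rng.standard_normal(5000))
        assert 0 < s.mc_error < s.sd


def _draws_from(chains_dict, config=None):
    """Assemble a PosteriorDraws by hand for diagnostic tests."""
    c, t = chains_dict["mu"].shape
    n_stud = 1
    n_rec = chains_dict.get("rho_ml", np.full((c, t, 1), 0.1)).shape[2]
    return PosteriorDraws(
        mu=chains_dict["mu"],
        sigma_b=chains_dict.get("sigma_b", np.ones((c, t))),
        sigma_w=chains_dict.get("sigma_w", np.ones((c, t))),
        mu_m=np.zeros((c, t, n_stud)),
        rho_ml=chains_dict.get("rho_ml", np.full((c, t, 1), 0.1)),
        rho_star=chains_dict.get("rho_star", np.full((c, t), 0.1)),
        study_ids=("A",),
        record_ids=(("A", "A.1"),),
        acceptance=np.full((c, n_rec), 0.3),
        config=config or ModelConfig(n_iter=t + 1, n_burnin=0, n_chains=c),
    )


class TestDiagnostics:
    def test_identical_stationary_chains_rhat_one(self, rng):
        x = rng.standard_normal(600)
        d = _draws_from({"mu": np.stack([x, x])})
        diag = convergence_diagnostics(d)
        assert diag.loc["mu", "rhat"] == 1.0

    def test_separated_constant_chains_rhat_huge(self):
        d = _draws_from({"mu": np.stack([np.zeros(400), np.ones(400)])})
        diag = convergence_diagnostics(d)
        assert diag.loc["mu", "rhat"] > 10
        assert not diag.attrs["converged"]

    def test_single_short_chain_rejected(self, rng):
        d = _draws_from({"mu": rng.standard_normal((1, 100))})
        with pytest.raises(ValueError, match="200"):
            convergence_diagnostics(d)

    def test_fixture_run_converges(self, table1):
        d = fit_model(table1, ModelConfig(n_chains=2, n_iter=6000, n_burnin=2000, seed=1))
        diag = convergence_diagnostics(d)
        assert diag.attrs["converged"]
        assert (diag["rhat"] <= 1.05).all()


class TestDIC:
    def test_degenerate_posterior_zero_pd(self):
        t = _single_record_table(icc=0.1)
        c, n = 1, 300
        d = _draws_from(
            {"mu": np.zeros((c, n)), "rho_ml": np.full((c, n, 1), 0.1)},
            config=ModelConfig(n_iter=n + 1, n_burnin=0, n_chains=c),
        )
        out = dic(d, t)
        assert out["p_d"] == pytest.approx(0.0, abs=1e-9)
        assert out["dic"] == pytest.approx(out["mean_deviance"])

    def test_effective_parameter_count_near_one(self):
        # a single record with a huge trial: the likelihood dominates the
        # hierarchy, so the latent ICC is one effective free parameter
        t = _single_record_table(icc=0.05, n=100_000, k=1000)
        d = fit_model(t, ModelConfig(n_chains=2, n_iter=8000, n_burnin=2000, seed=6))
        out = dic(d, t)
        assert out["p_d"] == pytest.approx(1.0, abs=0.3)

    def test_dimension_mismatch(self, table1):
        t = _single_record_table()
        d = fit_model(t, ModelConfig(n_chains=1, n_iter=1500, n_burnin=500, seed=1))
        with pytest.raises(ValueError, match="record count"):
            dic(d, table1)

    def test_subset_refit_comparison_runs(self, table1):
        # sensitivity-style comparison: full table vs most-relevant subset
        cfg = ModelConfig(n_chains=1, n_iter=2000, n_burnin=500, seed=9)
        full = dic(fit_model(table1, cfg), table1, cfg)
        from iccpool.study_io import StudyTable

        subset = StudyTable(table1.studies[:4])
        sub = dic(fit_model(subset, cfg), subset, cfg)
        assert np.isfinite(full["dic"]) and np.isfinite(sub["dic"])
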