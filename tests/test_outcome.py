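"""Weighted Weibull outcome model: likelihood, sampler, pooling, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bayestte as bt
from bayestte.outcome import (
    WeibullParams,
    fit_outcome_posterior,
    outcome_design,
    outcome_param_names,
    pool_posteriors,
    summarize_posterior,
    weibull_ml_fit,
    weighted_weibull_loglik,
)
from bayestte.weighting import WeightSet


def brute_force_loglik(params, times, events, X, weights):
    """Independent term-by-term scalar summation oracle."""
    k, lam = params.shape, np.exp(params.intercept)
    total = 0.0
    for i in range(len(times)):
        lp = float(np.dot(X[i], params.coefficients))
        t = times[i]
        if events[i]:
            total += weights[i] * (np.log(k) + np.log(lam) + (k - 1) * np.log(t) + lp)
        total -= weights[i] * lam * t**k * np.exp(lp)
    return total


class TestLoglik:
    def test_unit_subject_closed_form(self):
        """t=1, event, k=1, lam=1, beta=0, w=1: h(1)=1, H(1)=1 -> loglik -1."""
        params = WeibullParams(shape=1.0, intercept=0.0, coefficients=np.zeros(2))
        ll = weighted_weibull_loglik(params, np.array([1.0]), np.array([1]),
                                     np.zeros((1, 2)), np.array([1.0]))
        assert ll == pytest.approx(-1.0)

    def test_weight_doubling_equals_duplication(self, rng):
        params = WeibullParams(shape=1.2, intercept=-0.5, coefficients=np.array([0.3, -0.2]))
        t, d, x = np.array([2.0]), np.array([1]), rng.normal(size=(1, 2))
        double = weighted_weibull_loglik(params, t, d, x, np.array([2.0]))
        two_copies = weighted_weibull_loglik(
            params, np.repeat(t, 2), np.repeat(d, 2), np.repeat(x, 2, axis=0), np.ones(2))
        assert double == pytest.approx(two_copies, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        """20 subjects, mixed censoring, random weights: agreement to 1e-10."""
        n, p = 20, 4
        params = WeibullParams(shape=0.8, intercept=-1.0, coefficients=rng.normal(size=p))
        times = rng.uniform(0.1, 5.0, n)
        events = rng.integers(0, 2, n)
        X = rng.normal(size=(n, p))
        w = rng.uniform(0.5, 3.0, n)
        fast = weighted_weibull_loglik(params, times, events, X, w)
        slow = brute_force_loglik(params, times, events, X, w)
        assert fast == pytest.approx(slow, abs=1e-10)

    def test_nonpositive_shape_returns_neg_inf(self):
        params = WeibullParams(shape=-1.0, intercept=0.0, coefficients=np.zeros(1))
        ll = weighted_weibull_loglik(params, np.ones(1), np.ones(1, dtype=int),
                                     np.zeros((1, 1)), np.ones(1))
        assert ll == -np.inf

    def test_zero_time_censored_contributes_nothing(self):
        params = WeibullParams(shape=1.5, intercept=0.3, coefficients=np.zeros(1))
        with_zero = weighted_weibull_loglik(
            params, np.array([0.0, 2.0]), np.array([0, 1]), np.zeros((2, 1)), np.ones(2))
        without = weighted_weibull_loglik(
            params, np.array([2.0]), np.array([1]), np.zeros((1, 1)), np.ones(1))
        assert with_zero == pytest.approx(without)


class TestMlFitAftDuality:
    def test_ph_fit_matches_lifelines_aft_transform(self, cohort2000):
        """Independent oracle: lifelines' Weibull AFT fit transformed through
        beta_PH = -k * beta_AFT reproduces the PH maximum-likelihood fit."""
        from lifelines import WeibullAFTFitter

        sub = cohort2000.iloc[:600]
        covs = ["arm", "age", "tumor_size", "portal_htn"]
        X = sub[covs].to_numpy(dtype=float)
        times = sub["followup_years"].to_numpy() + 1e-6  # lifelines wants t > 0
        events = sub["event"].to_numpy()
        params, _, ok = weibull_ml_fit(times, events, X)
        assert ok

        df = sub[covs].copy()
        df["T"], df["E"] = times, events
        aft = WeibullAFTFitter(penalizer=0.0).fit(df, "T", "E")
        rho = float(np.exp(aft.params_[("rho_", "Intercept")]))
        assert params.shape == pytest.approx(rho, rel=0.01)
        for j, cov in enumerate(covs):
            beta_ph = -rho * float(aft.params_[("lambda_", cov)])
            assert params.coefficients[j] == pytest.approx(beta_ph, abs=0.01), cov


class TestPosteriorFit:
    def test_treatment_effect_recovery_unit_weights(self, cohort2000):
        """True log HR 0.30, near-flat prior, unit weights: recovered within 3 SD."""
        prior = bt.PriorSpec(treatment_mean=0.0, treatment_sd=10.0)
        ws = WeightSet(0, np.ones(len(cohort2000)), np.inf)
        draws, names, acc = fit_outcome_posterior(
            cohort2000, ws, prior, bt.McmcConfig(6000, 3000, 1, seed=7))
        j = names.index("arm")
        post = draws[:, j]
        assert abs(post.mean() - 0.30) < 3 * post.std(ddof=1)
        assert 0.1 < acc < 0.6

    def test_shape_recovery(self, criteria):
        """Data simulated at k = 1.3: posterior mean of k lands in (1.15, 1.45)."""
        config = bt.GeneratorConfig(n=2000, seed=61, shape=1.3)
        records = bt.generate_registry(config)
        subjects, _ = bt.apply_eligibility(records, criteria)
        cohort, _ = bt.build_analysis_frame(subjects)
        prior = bt.PriorSpec()
        ws = WeightSet(0, np.ones(len(cohort)), np.inf)
        draws, names, _ = fit_outcome_posterior(
            cohort, ws, prior, bt.McmcConfig(6000, 3000, 1, seed=9))
        k_post = np.exp(draws[:, names.index("log_shape")])
        assert 1.15 < k_post.mean() < 1.45

    def test_exponential_reduction(self, criteria):
        """Data simulated at k = 1: the shape posterior covers 1."""
        config = bt.GeneratorConfig(n=1500, seed=67, shape=1.0)
        records = bt.generate_registry(config)
        subjects, _ = bt.apply_eligibility(records, criteria)
        cohort, _ = bt.build_analysis_frame(subjects)
        ws = WeightSet(0, np.ones(len(cohort)), np.inf)
        draws, names, _ = fit_outcome_posterior(
            cohort, ws, bt.PriorSpec(), bt.McmcConfig(4000, 2000, 1, seed=10))
        lo, hi = np.quantile(draws[:, names.index("log_shape")], [0.025, 0.975])
        assert lo < 0.0 < hi

    def test_degenerate_prior_dominates(self, cohort2000):
        """s0 -> 1e-6 at m0 = 0.5 pins the treatment posterior at 0.5."""
        prior = bt.PriorSpec(treatment_mean=0.5, treatment_sd=1e-6)
        ws = WeightSet(0, np.ones(len(cohort2000)), np.inf)
        draws, names, _ = fit_outcome_posterior(
            cohort2000, ws, prior, bt.McmcConfig(2000, 1000, 1, seed=11))
        post = draws[:, names.index("arm")]
        assert abs(post.mean() - 0.5) < 1e-3

    def test_all_censored_warns(self):
        n = 40
        rng = np.random.default_rng(5)
        cohort = pd.DataFrame({name: rng.normal(size=n) for name in bt.OUTCOME_COVARIATES})
        cohort["arm"] = rng.integers(0, 2, n)
        cohort["followup_years"] = rng.uniform(0.5, 3.0, n)
        cohort["event"] = 0
        ws = WeightSet(0, np.ones(n), np.inf)
        with pytest.warns(RuntimeWarning, match="no events"):
            draws, names, _ = fit_outcome_posterior(
                cohort, ws, bt.PriorSpec(), bt.McmcConfig(500, 100, 1, seed=12))
        assert np.all(np.isfinite(draws))


class TestPoolingAndSummaries:
    def _draws(self, rows, p=3, fill=0.0):
        return np.full((rows, p), fill), [f"b{j}" for j in range(3)]

    def test_pool_sizes(self):
        pooled = pool_posteriors([self._draws(5), self._draws(5, fill=1.0)])
        assert pooled.draws.shape == (10, 3)
        assert pooled.set_index.tolist() == [0] * 5 + [1] * 5

    def test_pooling_with_itself_preserves_quantiles(self, rng):
        d = rng.normal(size=(200, 2)), ["a", "b"]
        once = pool_posteriors([d])
        twice = pool_posteriors([d, d])
        assert len(twice.draws) == 2 * len(once.draws)
        assert np.allclose(np.quantile(once.draws, [0.1, 0.5, 0.9], axis=0),
                           np.quantile(twice.draws, [0.1, 0.5, 0.9], axis=0))

    def test_full_scale_pooling_arithmetic(self):
        """The full protocol's pooled sample counts 500 x 10,000 draws."""
        mcmc = bt.McmcConfig(iterations=20_000, burn_in=10_000, thin=1)
        assert mcmc.retained == 10_000
        assert 500 * mcmc.retained == 5_000_000

    def test_mismatched_parameters_rejected(self):
        a = np.zeros((2, 3)), ["a", "b", "c"]
        b = np.zeros((2, 3)), ["a", "b", "d"]
        with pytest.raises(ValueError, match="names"):
            pool_posteriors([a, b])

    def test_constant_draws_summary(self):
        draws = pool_posteriors([(np.full((50, 1), 0.7), ["arm"])])
        row = summarize_posterior(draws).row("arm")
        for col in ("median", "mean", "cri_low", "cri_high"):
            assert row[col] == pytest.approx(0.7, abs=1e-12)

    def test_hr_transforms(self, rng):
        draws = pool_posteriors([(rng.normal(0.3, 0.08, size=(4000, 1)), ["arm"])])
        row = summarize_posterior(draws).row("arm")
        assert row["hr"] == pytest.approx(np.exp(row["median"]))
        assert row["hr_low"] == pytest.approx(np.exp(row["cri_low"]))
        assert row["cri_low"] <= row["median"] <= row["cri_high"]

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(bt.OutcomeDraws(np.zeros((0, 1)), ["a"], np.zeros(0)))
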