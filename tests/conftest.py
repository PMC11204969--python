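"""Shared fixtures: synthetic cohorts at the sizes the checks need.

Heavy fixtures are session-scoped so MCMC-based tests share one cohort
and, where possible, one posterior fit.
"""

from __future__ import annotations

import numpy as np
import pytest

import bayestte as bt


@pytest.fixture(scope="session")
def criteria() -> bt.EligibilityCriteria:
    return bt.EligibilityCriteria()


@pytest.fixture(scope="session")
def prior() -> bt.PriorSpec:
    return bt.build_treatment_prior(1.631, 0.497)


@pytest.fixture(scope="session")
def cohort2000(criteria):
    """Confounded analysis cohort of ~2000 subjects (all registry records eligible)."""
    config = bt.GeneratorConfig(n=2000, seed=20_240_522)
    records = bt.generate_registry(config)
    subjects, _ = bt.apply_eligibility(records, criteria)
    frame, scaling = bt.build_analysis_frame(subjects)
    return frame


@pytest.fixture(scope="session")
def ps_draws_2000(cohort2000, prior):
    """Moderate-length propensity posterior on the shared cohort."""
    mcmc = bt.McmcConfig(iterations=6000, burn_in=3000, thin=10, seed=5)
    return bt.fit_ps_posterior(cohort2000, prior, mcmc)


@pytest.fixture(scope="session")
def weight_sets_2000(cohort2000, ps_draws_2000):
    arms = cohort2000["arm"].to_numpy()
    return [
        bt.compute_stabilized_weights(s, arms, draw_index=i)
        for i, s in enumerate(ps_draws_2000.scores[:25])
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
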