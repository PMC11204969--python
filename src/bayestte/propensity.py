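"""Bayesian logistic treatment-assignment model.

Samples the posterior of a logistic regression of treatment arm on the
baseline confounders under independent diffuse normal priors
(mean 0, variance 100 per coefficient), then thins the chain to a set of
retained coefficient draws, each of which induces one propensity-score
vector over the cohort.  Propagating many score draws — rather than one
point estimate — is what lets downstream weighting carry the uncertainty
of the propensity model into the treatment-effect posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .config import PS_COVARIATES, McmcConfig
from .mcmc import adaptive_metropolis, thin_draws
from .priors import PriorSpec

__all__ = ["PsDraws", "design_matrix", "fit_ps_posterior", "logistic_ml_fit"]


@dataclass
class PsDraws:
    """Retained posterior draws of the propensity model.

    ``coefficients`` is (retained, p); ``scores`` is (retained, n) with
    scores[d, i] = logit^{-1}(x_i' gamma_d), strictly inside (0, 1).
    """

    coefficients: np.ndarray
    scores: np.ndarray
    param_names: list[str]
    acceptance_rate: float
    chain_labels: np.ndarray
    #: post-burn-in unthinned chains, shape (chains, iterations - burn_in, p);
    #: kept for convergence diagnostics
    post_burn_chains: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.scores <= 0) or np.any(self.scores >= 1):
            raise ValueError("propensity scores must lie strictly in (0, 1)")


def design_matrix(cohort: pd.DataFrame, covariates=PS_COVARIATES) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design matrix; errors on rank deficiency."""
    X = np.column_stack(
        [np.ones(len(cohort))] + [cohort[c].to_numpy(dtype=float) for c in covariates]
    )
    names = ["intercept"] + list(covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def logistic_ml_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ML logistic fit; returns (coefficients, covariance).

    Complete separation makes the ML estimate diverge; the diffuse prior
    still yields a proper posterior, so separation is reported as a
    warning and a ridge-stabilized fit is used for initialization only.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if np.any(~np.isfinite(res.params)) or np.any(np.abs(res.params) > 50):
            raise np.linalg.LinAlgError
        return np.asarray(res.params), np.asarray(res.cov_params())
    except Exception:
        warnings.warn(
            "possible complete separation in the treatment model; "
            "falling back to a ridge-regularized initialization",
            RuntimeWarning,
        )
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
        params = np.asarray(res.params)
        return params, np.eye(X.shape[1]) * 0.1


def _log_posterior_factory(X: np.ndarray, y: np.ndarray, prior_variance: float):
    def log_post(gamma: np.ndarray) -> float:
        lp = X @ gamma
        # log-lik of Bernoulli(logit^{-1}(lp)) without overflow
        loglik = np.sum(y * lp - np.logaddexp(0.0, lp))
        logprior = -0.5 * np.sum(gamma**2) / prior_variance
        return loglik + logprior

    return log_post


def fit_ps_posterior(
    cohort: pd.DataFrame,
    prior: PriorSpec,
    mcmc: McmcConfig,
    jitter_inits: bool = True,
) -> PsDraws:
    """Sample the propensity posterior and return thinned score draws.

    The sampler is a preconditioned adaptive random-walk Metropolis
    initialized at the ML estimate (chains beyond the first are jittered
    around it).  With the full-scale protocol — 10,000 iterations, 5,000
    burn-in, thin 10 — exactly 500 coefficient/score sets are retained
    per chain.  Draws from all chains are pooled in chain order and
    labelled, so single-chain production runs and multi-chain diagnostic
    runs share one code path.
    """
    X, names = design_matrix(cohort)
    y = cohort["arm"].to_numpy(dtype=float)
    ml_coef, ml_cov = logistic_ml_fit(X, y)
    log_post = _log_posterior_factory(X, y, prior.ps_prior_variance)

    rng = np.random.default_rng(mcmc.seed)
    kept, labels, acc_rates, post_burn = [], [], [], []
    for c in range(mcmc.chains):
        x0 = ml_coef.copy()
        if jitter_inits and c > 0:
            x0 = x0 + rng.multivariate_normal(np.zeros(len(x0)), ml_cov)
        chain, acc = adaptive_metropolis(
            log_post,
            x0,
            mcmc.iterations,
            mcmc.burn_in,
            rng,
            preconditioner=ml_cov,
            target_acceptance=mcmc.target_acceptance,
            initial_scale=mcmc.initial_scale,
        )
        retained = thin_draws(chain, mcmc.burn_in, mcmc.thin)
        kept.append(retained)
        labels.append(np.full(len(retained), c))
        acc_rates.append(acc)
        post_burn.append(chain[mcmc.burn_in :])

    coefficients = np.vstack(kept)
    scores = expit(coefficients @ X.T)
    eps = np.finfo(float).tiny
    scores = np.clip(scores, eps, 1 - eps)
    return PsDraws(
        coefficients=coefficients,
        scores=scores,
        param_names=names,
        acceptance_rate=float(np.mean(acc_rates)),
        chain_labels=np.concatenate(labels),
        post_burn_chains=np.stack(post_burn),
    )
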