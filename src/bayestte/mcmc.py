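"""Adaptive random-walk Metropolis engine and chain utilities.

Both Bayesian models in the pipeline (logistic treatment assignment and
weighted Weibull survival) have log-concave-ish, low-dimensional
posteriors without closed forms.  They are sampled with a preconditioned
Gaussian random-walk Metropolis sampler: the proposal covariance is a
fixed preconditioner (typically the inverse observed information at the
ML estimate) scaled by ``2.38**2 / d``, with a scalar step-size adapted
by Robbins–Monro toward a target acceptance rate during burn-in and
frozen thereafter, so the post-burn-in chain is a valid Markov chain
with the exact posterior as its stationary law.

Convergence is assessed with the classic (non-split) Gelman–Rubin
potential scale reduction factor computed from several independent
chains.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["adaptive_metropolis", "thin_draws", "gelman_rubin"]


def adaptive_metropolis(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    iterations: int,
    burn_in: int,
    rng: np.random.Generator,
    preconditioner: np.ndarray | None = None,
    target_acceptance: float = 0.234,
    initial_scale: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Run one chain; return (full chain of shape (iterations, d), post-burn-in acceptance rate).

    ``preconditioner`` is a d x d covariance whose Cholesky factor shapes
    the proposal; identity when omitted.  Step size is adapted only
    during the first ``burn_in`` iterations.
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    if preconditioner is None:
        chol = np.eye(d)
    else:
        # jitter for numerical positive-definiteness
        chol = np.linalg.cholesky(preconditioner + 1e-10 * np.eye(d))
    log_scale = np.log(initial_scale * 2.38 / np.sqrt(d))
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the initial point")

    chain = np.empty((iterations, d))
    accepted_post = 0
    for i in range(iterations):
        prop = x + np.exp(log_scale) * (chol @ rng.standard_normal(d))
        lp_prop = log_post(prop)
        log_alpha = lp_prop - lp
        accept = np.log(rng.uniform()) < log_alpha
        if accept:
            x, lp = prop, lp_prop
        if i < burn_in:
            # Robbins–Monro step-size adaptation, frozen at end of burn-in
            alpha = np.exp(min(log_alpha, 0.0)) if not np.isnan(log_alpha) else 0.0
            log_scale += (alpha - target_acceptance) / (i + 1) ** 0.6
        elif accept:
            accepted_post += 1
        chain[i] = x
    denom = max(iterations - burn_in, 1)
    return chain, accepted_post / denom


def thin_draws(raw_chain: np.ndarray, burn_in: int, thin: int) -> np.ndarray:
    """Discard ``burn_in`` draws then keep every ``thin``-th of the rest.

    In one-based chain indexing the retained draws are
    ``burn_in + thin, burn_in + 2*thin, ...``; the count is
    ``floor((len - burn_in) / thin)``.
    """
    raw_chain = np.asarray(raw_chain)
    length = raw_chain.shape[0]
    if burn_in >= length:
        raise ValueError(f"burn_in {burn_in} >= chain length {length}")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if length < burn_in + thin:
        raise ValueError("chain too short to retain any draw")
    return raw_chain[burn_in + thin - 1 :: thin]


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Classic Gelman–Rubin PSRF per parameter.

    ``chains`` has shape (m, n, p): m >= 2 chains of equal length n >= 2.
    For each parameter, with W the mean within-chain variance and B/n the
    between-chain variance of the chain means,

        R_hat = sqrt(((n - 1)/n * W + B/n) / W).

    Identical chains give ``sqrt((n - 1)/n)`` (slightly below 1); values
    near 1 indicate convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[..., None]
    if chains.ndim != 3:
        raise ValueError("chains must have shape (m, n, p)")
    m, n, _ = chains.shape
    if m < 2:
        raise ValueError("PSRF needs at least 2 chains")
    if n < 2:
        raise ValueError("PSRF needs chain length >= 2")
    within = chains.var(axis=1, ddof=1).mean(axis=0)          # W, per parameter
    means = chains.mean(axis=1)                                # (m, p)
    b_over_n = means.var(axis=0, ddof=1)                       # B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((n - 1) / n * within + b_over_n) / within)
    return np.where(within == 0, np.where(b_over_n == 0, np.sqrt((n - 1) / n), np.inf), rhat)
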