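"""Stabilized, truncated inverse-probability-of-treatment weights and balance.

Each retained propensity-score draw is turned into one weight vector —
one pseudo-population in which baseline confounders are unassociated
with the received treatment.  Raw weights are 1/e for the ablation arm
and 1/(1 - e) for the hepatectomy arm; stabilization multiplies by the
marginal arm share (keeping the arm size ratio), and weights above the
cohort's upper 99.5th percentile within a weight set are capped at that
percentile to avoid giving extreme influence to single subjects.

Balance is quantified by the absolute standardized mean difference

    d_j = |xbar_1 - xbar_0| / sqrt((s_1**2 + s_0**2) / 2)

with weighted means and frequency-weighted variances per arm; d_j < 0.1
is the conventional threshold for adequate balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PS_COVARIATES

__all__ = ["WeightSet", "BalanceTable", "compute_stabilized_weights", "weighted_smd", "balance_over_draws"]


@dataclass
class WeightSet:
    """One stabilized, truncated IPT weight vector (one pseudo-population)."""

    draw_index: int
    weights: np.ndarray
    truncation_threshold: float
    stabilized: bool = True


@dataclass
class BalanceTable:
    """Per-covariate absolute SMD before and after weighting."""

    table: pd.DataFrame  # columns: covariate, smd_unweighted, smd_weighted

    @property
    def frac_balanced(self) -> float:
        """Share of covariates with weighted SMD below 0.1."""
        return float((self.table["smd_weighted"] < 0.1).mean())


def compute_stabilized_weights(
    scores: np.ndarray,
    arms: np.ndarray,
    truncate_pct: float = 99.5,
    draw_index: int = 0,
) -> WeightSet:
    """Stabilized IPT weights from one propensity-score vector.

    ``scores`` are P(ablation | x) in the open interval (0, 1); ``arms``
    is the 0/1 ablation indicator.  The truncation percentile is taken
    over the combined cohort within this weight set.
    """
    scores = np.asarray(scores, dtype=float)
    arms = np.asarray(arms)
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    if scores.shape != arms.shape:
        raise ValueError("scores and arms misaligned")
    p_treated = arms.mean()
    raw = np.where(arms == 1, 1.0 / scores, 1.0 / (1.0 - scores))
    stabilized = np.where(arms == 1, p_treated, 1.0 - p_treated) * raw
    threshold = float(np.percentile(stabilized, truncate_pct))
    return WeightSet(
        draw_index=draw_index,
        weights=np.minimum(stabilized, threshold),
        truncation_threshold=threshold,
    )


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    var = float(np.sum(w * (x - mean) ** 2) / wsum)  # frequency-weight normalization
    return mean, var


def weighted_smd(
    cohort: pd.DataFrame,
    weights: np.ndarray | None = None,
    covariates=PS_COVARIATES,
) -> pd.Series:
    """Absolute standardized mean difference per covariate under given weights.

    ``weights=None`` means unit weights (the unweighted SMD).  A zero
    pooled variance yields 0 when the arm means agree and inf otherwise.
    """
    arms = cohort["arm"].to_numpy()
    w = np.ones(len(cohort)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape[0] != len(cohort):
        raise ValueError("weights misaligned with cohort")
    out = {}
    for cov in covariates:
        x = cohort[cov].to_numpy(dtype=float)
        m1, v1 = _weighted_mean_var(x[arms == 1], w[arms == 1])
        m0, v0 = _weighted_mean_var(x[arms == 0], w[arms == 0])
        pooled = (v1 + v0) / 2.0
        if pooled == 0:
            out[cov] = 0.0 if m1 == m0 else np.inf
        else:
            out[cov] = abs(m1 - m0) / np.sqrt(pooled)
    return pd.Series(out, name="smd")


def balance_over_draws(
    cohort: pd.DataFrame,
    weight_sets: list[WeightSet],
    covariates=PS_COVARIATES,
) -> BalanceTable:
    """SMD before weighting and averaged over all pseudo-populations."""
    before = weighted_smd(cohort, None, covariates)
    after = sum(weighted_smd(cohort, ws.weights, covariates) for ws in weight_sets) / len(weight_sets)
    table = pd.DataFrame(
        {"covariate": list(covariates), "smd_unweighted": before.values, "smd_weighted": after.values}
    )
    return BalanceTable(table=table)
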