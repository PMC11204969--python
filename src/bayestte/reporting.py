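"""Descriptive statistics, unweighted survival comparison and the frequentist comparator.

Kaplan–Meier estimation and the log-rank test are delegated to
lifelines; the frequentist comparator mirrors the Bayesian pipeline with
point estimates — one ML logistic propensity fit, one stabilized and
truncated weight vector, one weighted ML Weibull fit with Wald
intervals — and is reported purely as a baseline against which the
Bayesian uncertainty propagation can be judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.special import expit

from .config import BINARY_COVARIATES, CONTINUOUS_COVARIATES, PS_COVARIATES
from .outcome import outcome_design, outcome_param_names, weibull_ml_fit
from .propensity import design_matrix, logistic_ml_fit
from .weighting import compute_stabilized_weights

__all__ = [
    "KmCurve",
    "km_estimate",
    "logrank_test",
    "format_count",
    "descriptive_table",
    "frequentist_comparator",
]


@dataclass
class KmCurve:
    """Product-limit survival curve for one arm."""

    arm: str
    times: np.ndarray
    survival: np.ndarray
    median_years: float | None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival function must be nonincreasing")


def km_estimate(times: np.ndarray, events: np.ndarray, label: str = "") -> KmCurve:
    """Kaplan–Meier curve and median survival (first time S(t) <= 0.5)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty arm")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or None)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KmCurve(arm=label, times=grid, survival=surv, median_years=median)


def logrank_test(times: np.ndarray, events: np.ndarray, arms: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    arms = np.asarray(arms)
    groups = np.unique(arms)
    if groups.size != 2:
        raise ValueError("log-rank test needs exactly two arms")
    m = arms == groups[0]
    if np.asarray(events).sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(
        np.asarray(times)[m], np.asarray(times)[~m],
        event_observed_A=np.asarray(events)[m], event_observed_B=np.asarray(events)[~m],
    )
    return float(res.test_statistic), float(res.p_value)


def format_count(count: int, total: int) -> str:
    """Render ``count (pct%)`` with the percentage at one decimal place."""
    pct = 100.0 * count / total if total else 0.0
    return f"{count} ({pct:.1f}%)"


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table: per-arm and total summaries with p-values.

    Binaries are shown as ``n (pct%)`` with chi-square p-values;
    continuous covariates as ``mean (sd)`` with two-sample t-test
    p-values.  Continuous covariates are assumed to be on the scale the
    cohort frame carries (standardized in the analysis frame; pass raw
    values for a publication-style table).
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    arms = cohort["arm"].to_numpy()
    n1, n0, n = int((arms == 1).sum()), int((arms == 0).sum()), len(cohort)
    rows = []
    for cov in CONTINUOUS_COVARIATES:
        x = cohort[cov]
        x1, x0 = x[arms == 1], x[arms == 0]
        p = stats.ttest_ind(x1, x0, equal_var=False).pvalue if min(len(x1), len(x0)) > 1 else np.nan
        rows.append({
            "variable": cov, "type": "continuous",
            "hepatectomy": f"{x0.mean():.1f} ({x0.std(ddof=1):.2f})",
            "ablation": f"{x1.mean():.1f} ({x1.std(ddof=1):.2f})",
            "total": f"{x.mean():.1f} ({x.std(ddof=1):.2f})",
            "p_value": float(p),
        })
    for cov in BINARY_COVARIATES:
        x = cohort[cov].to_numpy()
        c1, c0 = int(x[arms == 1].sum()), int(x[arms == 0].sum())
        contingency = np.array([[c1, n1 - c1], [c0, n0 - c0]])
        if contingency.min() >= 0 and contingency.sum(axis=1).min() > 0 and 0 < x.sum() < n:
            p = stats.chi2_contingency(contingency, correction=True).pvalue
        else:
            p = np.nan
        rows.append({
            "variable": cov, "type": "binary",
            "hepatectomy": format_count(c0, n0),
            "ablation": format_count(c1, n1),
            "total": format_count(c1 + c0, n),
            "p_value": float(p) if p == p else np.nan,
        })
    return pd.DataFrame(rows)


def frequentist_comparator(
    cohort: pd.DataFrame,
    truncate_pct: float = 99.5,
    unit_weights: bool = False,
) -> pd.DataFrame:
    """Point-estimate analogue of the Bayesian pipeline.

    Single ML logistic propensity fit, one stabilized/truncated weight
    vector from the fitted scores, then a weighted ML Weibull PH fit with
    Wald 95% confidence intervals.  ``unit_weights`` skips the weighting
    entirely (an unweighted Weibull regression).  Nonconvergence is
    reported in the ``converged`` column rather than raised.
    """
    X_ps, _ = design_matrix(cohort, PS_COVARIATES)
    y = cohort["arm"].to_numpy(dtype=float)
    if unit_weights:
        w = np.ones(len(cohort))
    else:
        coef, _ = logistic_ml_fit(X_ps, y)
        scores = expit(X_ps @ coef)
        eps = np.finfo(float).tiny
        scores = np.clip(scores, eps, 1 - eps)
        w = compute_stabilized_weights(scores, y.astype(int), truncate_pct).weights

    times = cohort["followup_years"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy()
    X = outcome_design(cohort)
    params, cov, converged = weibull_ml_fit(times, events, X, w)
    theta = params.as_vector()
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = stats.norm.ppf(0.975)
    names = outcome_param_names()
    out = pd.DataFrame({
        "parameter": names,
        "estimate": theta,
        "se": se,
        "ci_low": theta - z * se,
        "ci_high": theta + z * se,
        "converged": converged,
    })
    is_loghr = ~out["parameter"].isin(["log_shape", "intercept"])
    for src, dst in (("estimate", "hr"), ("ci_low", "hr_low"), ("ci_high", "hr_high")):
        out[dst] = np.where(is_loghr, np.exp(out[src]), np.nan)
    return out
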