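"""Prior elicitation from published hazard ratios.

A table of hazard ratios from earlier comparative studies is condensed
into a robust location/spread pair (median, unscaled median absolute
deviation) and mapped to a normal prior on the treatment log hazard
ratio.  The spread is transferred to the log scale by the delta method
(MAD divided by the median) and inflated by a user-set factor so the
prior stays weakly informative; a floor on the prior SD guarantees a
proper prior even when the literature is unanimous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LiteratureEvidence",
    "PriorSpec",
    "summarize_literature",
    "build_treatment_prior",
    "read_evidence",
]


@dataclass
class LiteratureEvidence:
    """Published hazard ratios: one row per study."""

    study_id: str
    hr: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError(f"study {self.study_id}: hr must be > 0")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low < self.hr < self.ci_high):
                raise ValueError(f"study {self.study_id}: CI must bracket the HR")


@dataclass
class PriorSpec:
    """All prior hyperparameters of the two Bayesian models.

    ``treatment_mean`` / ``treatment_sd`` parameterize the normal prior
    on the treatment log hazard ratio.  Covariate log-hazard effects get
    independent N(0, covariate_prior_sd**2) priors; the Weibull shape an
    Exp(shape_prior_rate) prior; propensity coefficients independent
    normals with variance ``ps_prior_variance``.
    """

    treatment_mean: float = 0.0
    treatment_sd: float = 10.0
    covariate_prior_sd: float = 10.0
    shape_prior_rate: float = 1.0
    ps_prior_variance: float = 100.0

    def __post_init__(self) -> None:
        for name in ("treatment_sd", "covariate_prior_sd", "shape_prior_rate", "ps_prior_variance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "treatment_mean": self.treatment_mean,
            "treatment_sd": self.treatment_sd,
            "covariate_prior_sd": self.covariate_prior_sd,
            "shape_prior_rate": self.shape_prior_rate,
            "ps_prior_variance": self.ps_prior_variance,
        }


def summarize_literature(evidence: list[LiteratureEvidence]) -> tuple[float, float]:
    """Median and raw (unscaled) MAD of the published hazard ratios.

    The MAD is ``median(|hr_i - median|)`` with no consistency factor:
    the summary describes the literature rather than estimating a normal
    scale.
    """
    if not evidence:
        raise ValueError("evidence table is empty")
    hrs = np.array([e.hr for e in evidence], dtype=float)
    med = float(np.median(hrs))
    mad = float(np.median(np.abs(hrs - med)))
    return med, mad


def build_treatment_prior(
    median_hr: float,
    mad_hr: float,
    inflation: float = 3.0,
    floor: float = 0.1,
    **kwargs,
) -> PriorSpec:
    """Turn a literature (median, MAD) pair into a treatment log-HR prior.

    The location is ``log(median_hr)``; the scale is
    ``inflation * mad_hr / median_hr`` (delta-method transfer of the HR
    spread to the log scale), floored at ``floor`` so the prior is always
    proper and weakly informative.  Extra keyword arguments pass through
    to :class:`PriorSpec` (e.g. ``covariate_prior_sd``).
    """
    if median_hr <= 0:
        raise ValueError("median_hr must be > 0")
    if mad_hr < 0:
        raise ValueError("mad_hr must be >= 0")
    if inflation < 1:
        raise ValueError("inflation must be >= 1")
    scale = max(inflation * mad_hr / median_hr, floor)
    return PriorSpec(treatment_mean=float(np.log(median_hr)), treatment_sd=scale, **kwargs)


def read_evidence(path: str | Path) -> list[LiteratureEvidence]:
    """Read an evidence CSV with columns study_id, hr[, ci_low, ci_high, p_value]."""
    frame = pd.read_csv(path)
    out = []
    for _, row in frame.iterrows():
        def _opt(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        out.append(
            LiteratureEvidence(
                study_id=str(row["study_id"]),
                hr=float(row["hr"]),
                ci_low=_opt("ci_low"),
                ci_high=_opt("ci_high"),
                p_value=_opt("p_value"),
            )
        )
    return out
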