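"""Configuration objects shared across the pipeline.

Three dataclasses describe everything the pipeline needs to know that is
not data: how to simulate a registry (:class:`GeneratorConfig`), how to
emulate the trial from it (:class:`EligibilityCriteria`), and how to run
the MCMC samplers (:class:`McmcConfig`).  All carry validated defaults
matching the study conditions of the analysis they support.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from typing import Mapping

__all__ = [
    "CONTINUOUS_COVARIATES",
    "BINARY_COVARIATES",
    "LIVER_FLAGS",
    "PS_COVARIATES",
    "OUTCOME_COVARIATES",
    "DEFAULT_COVARIATE_SPEC",
    "DEFAULT_PS_COEFFICIENTS",
    "DEFAULT_OUTCOME_COEFFICIENTS",
    "GeneratorConfig",
    "EligibilityCriteria",
    "McmcConfig",
]

#: continuous baseline covariates, modelled per standard deviation
CONTINUOUS_COVARIATES = ("age", "tumor_size", "elixhauser")

#: liver-disease indicator block (shares a latent severity factor in the generator)
LIVER_FLAGS = (
    "hep_b",
    "hep_c",
    "other_viral_hep",
    "nonviral_hep",
    "alcoholic_liver",
    "nonalc_cirrhosis",
    "portal_htn",
    "enceph",
)

BINARY_COVARIATES = ("female", "white", "married", "stage2") + LIVER_FLAGS

#: covariates entering the treatment-assignment (propensity) model.  Marital
#: status is deliberately absent: it is balanced between arms and enters the
#: outcome model only, to improve precision.
PS_COVARIATES = (
    "age",
    "female",
    "white",
    "stage2",
    "tumor_size",
    "elixhauser",
) + LIVER_FLAGS

#: covariates in the survival outcome model (treatment arm is added separately)
OUTCOME_COVARIATES = (
    "age",
    "female",
    "white",
    "married",
    "stage2",
    "tumor_size",
    "elixhauser",
) + LIVER_FLAGS

# Marginals of the target registry population: proportions for binaries,
# (mean, sd) for continuous covariates on their natural scales.
DEFAULT_COVARIATE_SPEC: Mapping[str, object] = {
    "age": (73.6, 5.64),
    "tumor_size": (29.3, 10.5),
    "elixhauser": (22.59, 8.89),
    "female": 0.376,
    "white": 0.531,
    "married": 0.585,
    "stage2": 0.291,
    "hep_b": 0.168,
    "hep_c": 0.465,
    "other_viral_hep": 0.073,
    "nonviral_hep": 0.196,
    "alcoholic_liver": 0.193,
    "nonalc_cirrhosis": 0.832,
    "portal_htn": 0.476,
    "enceph": 0.112,
}

# Treatment-assignment log-odds (ablation vs partial hepatectomy), per SD for
# continuous covariates.  The intercept is chosen so the marginal ablation
# share is roughly 0.74 under the default covariate marginals.
DEFAULT_PS_COEFFICIENTS: Mapping[str, float] = {
    "intercept": -0.37,
    "age": 0.25,
    "female": -0.16,
    "white": 0.00,
    "stage2": 0.19,
    "tumor_size": -0.52,
    "elixhauser": 0.06,
    "hep_b": -0.29,
    "hep_c": 0.12,
    "other_viral_hep": -0.06,
    "nonviral_hep": 0.37,
    "alcoholic_liver": 0.61,
    "nonalc_cirrhosis": 0.84,
    "portal_htn": 0.87,
    "enceph": 0.42,
}

# Log-hazard effects on overall survival, per SD for continuous covariates.
DEFAULT_OUTCOME_COEFFICIENTS: Mapping[str, float] = {
    "age": 0.24,
    "female": -0.09,
    "white": -0.01,
    "married": -0.18,
    "stage2": 0.15,
    "tumor_size": 0.15,
    "elixhauser": 0.19,
    "hep_b": -0.33,
    "hep_c": -0.03,
    "other_viral_hep": 0.26,
    "nonviral_hep": -0.19,
    "alcoholic_liver": 0.13,
    "nonalc_cirrhosis": 0.09,
    "portal_htn": 0.65,
    "enceph": 0.43,
}


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic registry generator.

    The defaults reproduce, at the level of marginals and coefficient
    scales, the registry population the analysis targets: elderly
    early-stage hepatocellular-carcinoma patients choosing between
    partial hepatectomy and ablation, with confounded treatment
    assignment and Weibull overall survival.
    """

    n: int = 2000
    covariate_spec: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_SPEC)
    )
    ps_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PS_COEFFICIENTS)
    )
    outcome_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS)
    )
    #: log hazard ratio of ablation vs partial hepatectomy
    true_log_hr: float = 0.30
    #: Weibull shape k (> 0); k = 1 is exponential survival
    shape: float = 1.1
    #: log of the Weibull rate parameter at covariate means, reference arm
    baseline_log_rate: float = -2.55
    #: accrual window for diagnosis dates
    accrual_start: dt.date = dt.date(2007, 1, 1)
    accrual_end: dt.date = dt.date(2017, 12, 31)
    #: administrative censoring date
    study_end: dt.date = dt.date(2019, 12, 31)
    #: share of records deliberately violating one eligibility rule each
    ineligible_fraction: float = 0.0
    #: loading of the shared latent severity factor on the liver flags
    liver_loading: float = 0.5
    #: probability an ablation patient has a second ablation session
    repeat_ablation_prob: float = 0.10
    #: probability an eligible patient crosses over to the other procedure
    crossover_prob: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        _require(isinstance(self.n, int) and self.n > 0, "n must be a positive integer")
        _require(self.shape > 0, "shape must be > 0")
        _require(0 <= self.ineligible_fraction < 1, "ineligible_fraction must be in [0, 1)")
        _require(0 <= self.liver_loading < 1, "liver_loading must be in [0, 1)")
        _require(self.accrual_start <= self.accrual_end, "accrual window must be ordered")
        _require(self.accrual_end <= self.study_end, "study_end precedes accrual window")
        for name, value in self.covariate_spec.items():
            if name in CONTINUOUS_COVARIATES:
                mean, sd = value  # type: ignore[misc]
                _require(sd > 0, f"covariate_spec[{name!r}] needs sd > 0")
            else:
                _require(0 <= float(value) <= 1, f"covariate_spec[{name!r}] must be a proportion in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("accrual_start", "accrual_end", "study_end"):
            d[key] = d[key].isoformat()
        return d


@dataclass
class EligibilityCriteria:
    """Eligibility, time-zero and censoring rules of the emulated trial."""

    age_min: float = 66.0
    age_max: float = 100.0
    accrual_start: dt.date = dt.date(2007, 1, 1)
    accrual_end: dt.date = dt.date(2017, 12, 31)
    stages_allowed: tuple[str, ...] = ("I", "II")
    #: 50 mm for the main cohort, 30 mm for the small-tumor subgroup
    max_tumor_mm: float = 50.0
    #: first qualifying surgery must fall within this many days of diagnosis
    surgery_window_days: int = 365
    study_end: dt.date = dt.date(2019, 12, 31)

    def __post_init__(self) -> None:
        _require(self.age_min < self.age_max, "age range must be ordered")
        _require(self.max_tumor_mm > 0, "max_tumor_mm must be > 0")
        _require(self.surgery_window_days > 0, "surgery_window_days must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("accrual_start", "accrual_end", "study_end"):
            d[key] = d[key].isoformat()
        d["stages_allowed"] = list(self.stages_allowed)
        return d


@dataclass
class McmcConfig:
    """Settings for the adaptive random-walk Metropolis samplers.

    Full-scale defaults follow the analysis protocol: 10,000 iterations
    with 5,000 burn-in and thin 10 for the propensity model (500 retained
    score sets), 20,000 / 10,000 for the outcome model.
    """

    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    chains: int = 1
    seed: int = 0
    target_acceptance: float = 0.234
    #: initial scalar multiplier of the preconditioned proposal
    initial_scale: float = 1.0

    def __post_init__(self) -> None:
        _require(self.iterations > 0, "iterations must be positive")
        _require(0 <= self.burn_in < self.iterations, "burn_in must be < iterations")
        _require(self.thin >= 1, "thin must be >= 1")
        _require(self.chains >= 1, "chains must be >= 1")
        _require(0 < self.target_acceptance < 1, "target_acceptance must be in (0, 1)")

    @property
    def retained(self) -> int:
        """Number of retained draws per chain after burn-in and thinning."""
        return (self.iterations - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        return asdict(self)
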