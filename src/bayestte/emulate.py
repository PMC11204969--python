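"""Trial emulation: eligibility, treatment arms, time zero and censoring.

Builds the analysis cohort from a registry by applying the emulated
trial's rules in a fixed, documented order and logging per-rule
attrition the way a selection flowchart does (each excluded record is
attributed to the FIRST rule it fails).

Rule order:

1. ``malformed``       — unparseable or inconsistent dates (death before surgery)
2. ``enrollment``      — continuous-enrollment / registry exclusion flag
3. ``age``             — age at diagnosis outside [66, 100]
4. ``accrual``         — diagnosis outside the accrual window
5. ``missing``         — missing month of diagnosis, stage, or tumor size
6. ``stage``           — stage outside {I, II}
7. ``tumor_size``      — tumor larger than the cohort's size cap
8. ``surgery_window``  — no qualifying surgery within one year of diagnosis
9. ``same_day``        — both procedure types on the same (first) day

Time zero is the date of the first qualifying surgery (first ablation
session when ablation is repeated).  The arm is intention-to-treat: the
first procedure type received.  Follow-up runs to death, receipt of the
other procedure type, or the administrative study end, whichever comes
first; only death counts as an event.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_YEAR, PatientRecord
from .config import CONTINUOUS_COVARIATES, OUTCOME_COVARIATES, EligibilityCriteria

__all__ = [
    "RULE_ORDER",
    "EmulatedSubject",
    "ExclusionLog",
    "apply_eligibility",
    "define_followup",
    "build_analysis_frame",
]

RULE_ORDER = (
    "malformed",
    "enrollment",
    "age",
    "accrual",
    "missing",
    "stage",
    "tumor_size",
    "surgery_window",
    "same_day",
)


@dataclass
class EmulatedSubject:
    """One analysis row of the emulated trial."""

    id: int
    arm: str                    # "hepatectomy" or "ablation"
    time_zero: dt.date
    followup_years: float
    event: int
    censor_reason: str          # "death", "second_procedure", "admin_end"
    covariates: dict[str, float]


@dataclass
class ExclusionLog:
    """Per-rule attrition counts plus each record's first failing rule."""

    n_input: int = 0
    n_included: int = 0
    counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})
    reasons: dict[int, str] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_included

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "counts": dict(self.counts),
        }


def _first_failing_rule(rec: PatientRecord, criteria: EligibilityCriteria) -> str | None:
    """Return the first rule (in RULE_ORDER) the record fails, or None."""
    surgeries = sorted(rec.surgeries, key=lambda s: (s[1], s[0]))
    if rec.diagnosis_date is None or any(d is None for _, d in surgeries):
        return "malformed"
    if rec.death_date is not None and rec.death_date < rec.diagnosis_date:
        return "malformed"
    if not rec.enrollment_ok:
        return "enrollment"
    if not (criteria.age_min <= rec.age_at_diagnosis <= criteria.age_max):
        return "age"
    if not (criteria.accrual_start <= rec.diagnosis_date <= criteria.accrual_end):
        return "accrual"
    if (not rec.month_known) or rec.stage is None or rec.tumor_size_mm is None:
        return "missing"
    if rec.stage not in criteria.stages_allowed:
        return "stage"
    if rec.tumor_size_mm > criteria.max_tumor_mm:
        return "tumor_size"
    window_end = rec.diagnosis_date + dt.timedelta(days=criteria.surgery_window_days)
    qualifying = [s for s in surgeries if rec.diagnosis_date <= s[1] <= window_end]
    if not qualifying:
        return "surgery_window"
    t0 = qualifying[0][1]
    procs_on_t0 = {p for p, d in qualifying if d == t0}
    if len(procs_on_t0) > 1:
        return "same_day"
    return None


def define_followup(
    rec: PatientRecord, criteria: EligibilityCriteria
) -> tuple[dt.date, str, float, int, str]:
    """Derive (time_zero, arm, followup_years, event, censor_reason).

    Follow-up ends at the earliest of death, first receipt of the other
    procedure type, and the administrative study end; ties are broken
    death > second_procedure > admin_end.  Raises on a death recorded
    before time zero (corrupt record).
    """
    window_end = rec.diagnosis_date + dt.timedelta(days=criteria.surgery_window_days)
    qualifying = sorted(
        (s for s in rec.surgeries if rec.diagnosis_date <= s[1] <= window_end),
        key=lambda s: (s[1], s[0]),
    )
    if not qualifying:
        raise ValueError(f"record {rec.id}: no qualifying surgery")
    arm, time_zero = qualifying[0]
    if rec.death_date is not None and rec.death_date < time_zero:
        raise ValueError(f"record {rec.id}: death precedes surgery")

    second = min(
        (d for p, d in rec.surgeries if p != arm and d >= time_zero),
        default=None,
    )
    candidates: list[tuple[dt.date, str]] = [(criteria.study_end, "admin_end")]
    if second is not None:
        candidates.append((second, "second_procedure"))
    if rec.death_date is not None:
        candidates.append((rec.death_date, "death"))
    priority = {"death": 0, "second_procedure": 1, "admin_end": 2}
    end, reason = min(candidates, key=lambda c: (c[0], priority[c[1]]))
    days = max((end - time_zero).days, 0)
    event = int(reason == "death")
    if event and days == 0:
        days = 0.5  # same-day death: half-day convention keeps event times positive
    followup = days / DAYS_PER_YEAR
    return time_zero, arm, followup, event, reason


def apply_eligibility(
    records: list[PatientRecord], criteria: EligibilityCriteria
) -> tuple[list[EmulatedSubject], ExclusionLog]:
    """Apply the emulated trial's rules, returning subjects and an attrition log.

    A record is enrolled iff it passes every rule; each excluded record is
    logged under its first failing rule.  Raw (unstandardized) covariates
    are attached to each subject; standardization happens cohort-wide in
    :func:`build_analysis_frame`.
    """
    log = ExclusionLog(n_input=len(records))
    subjects: list[EmulatedSubject] = []
    for rec in records:
        rule = _first_failing_rule(rec, criteria)
        if rule is None:
            try:
                time_zero, arm, fu, event, reason = define_followup(rec, criteria)
            except ValueError:
                rule = "malformed"
        if rule is not None:
            log.counts[rule] += 1
            log.reasons[rec.id] = rule
            continue
        covs = {
            "age": rec.age_at_diagnosis,
            "female": float(rec.female),
            "white": float(rec.white),
            "married": float(rec.married),
            "stage2": float(rec.stage == "II"),
            "tumor_size": float(rec.tumor_size_mm),
            "elixhauser": rec.elixhauser,
            "hep_b": float(rec.hep_b),
            "hep_c": float(rec.hep_c),
            "other_viral_hep": float(rec.other_viral_hep),
            "nonviral_hep": float(rec.nonviral_hep),
            "alcoholic_liver": float(rec.alcoholic_liver),
            "nonalc_cirrhosis": float(rec.nonalc_cirrhosis),
            "portal_htn": float(rec.portal_htn),
            "enceph": float(rec.enceph),
        }
        subjects.append(
            EmulatedSubject(
                id=rec.id,
                arm=arm,
                time_zero=time_zero,
                followup_years=fu,
                event=event,
                censor_reason=reason,
                covariates=covs,
            )
        )
    log.n_included = len(subjects)
    return subjects, log


def build_analysis_frame(
    subjects: list[EmulatedSubject],
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Assemble the analysis table, standardizing continuous covariates.

    Continuous covariates (age, tumor size, comorbidity score) are
    centred and scaled by the eligible cohort's mean and SD so model
    coefficients read per standard deviation; the (mean, sd) pairs are
    returned for back-transformation in reports.

    Returns a DataFrame with columns ``id``, ``arm`` (1 = ablation),
    ``followup_years``, ``event``, ``censor_reason`` and one column per
    covariate in :data:`~bayestte.config.OUTCOME_COVARIATES`.
    """
    if not subjects:
        raise ValueError("no subjects to analyse")
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "arm": int(s.arm == "ablation"),
            "followup_years": s.followup_years,
            "event": s.event,
            "censor_reason": s.censor_reason,
        }
        row.update({k: s.covariates[k] for k in OUTCOME_COVARIATES})
        rows.append(row)
    frame = pd.DataFrame(rows)
    scaling: dict[str, tuple[float, float]] = {}
    for name in CONTINUOUS_COVARIATES:
        mean = float(frame[name].mean())
        sd = float(frame[name].std(ddof=1))
        if sd == 0 or np.isnan(sd):
            sd = 1.0
        frame[name] = (frame[name] - mean) / sd
        scaling[name] = (mean, sd)
    return frame, scaling
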