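"""Trial emulation: eligibility rules, time zero, follow-up and censoring."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

import bayestte as bt
from bayestte.cohort import DAYS_PER_YEAR, PatientRecord
from bayestte.emulate import RULE_ORDER, apply_eligibility, build_analysis_frame, define_followup


def make_record(**overrides) -> PatientRecord:
    """A fully eligible reference record; overrides tweak single fields."""
    base = dict(
        id=0,
        age_at_diagnosis=72.0,
        female=1,
        white=1,
        married=0,
        diagnosis_date=dt.date(2010, 1, 1),
        month_known=True,
        stage="I",
        tumor_size_mm=30.0,
        surgeries=[("ablation", dt.date(2010, 3, 1))],
        elixhauser=20.0,
        hep_b=0, hep_c=1, other_viral_hep=0, nonviral_hep=0,
        alcoholic_liver=0, nonalc_cirrhosis=1, portal_htn=0, enceph=0,
        death_date=None,
        enrollment_ok=True,
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestEligibilityRules:
    @pytest.mark.parametrize(
        "overrides, rule",
        [
            ({"age_at_diagnosis": 65.0}, "age"),
            ({"age_at_diagnosis": 100.5}, "age"),
            ({"diagnosis_date": dt.date(2006, 12, 31),
              "surgeries": [("ablation", dt.date(2007, 2, 1))]}, "accrual"),
            ({"month_known": False}, "missing"),
            ({"stage": None}, "missing"),
            ({"tumor_size_mm": None}, "missing"),
            ({"stage": "other"}, "stage"),
            ({"tumor_size_mm": 51.0}, "tumor_size"),
            ({"surgeries": [("ablation", dt.date(2011, 1, 2))]}, "surgery_window"),
            ({"surgeries": []}, "surgery_window"),
            ({"surgeries": [("ablation", dt.date(2010, 3, 1)),
                            ("hepatectomy", dt.date(2010, 3, 1))]}, "same_day"),
            ({"enrollment_ok": False}, "enrollment"),
        ],
    )
    def test_single_violations_attributed_to_rule(self, criteria, overrides, rule):
        subjects, log = apply_eligibility([make_record(**overrides)], criteria)
        assert subjects == []
        assert log.counts[rule] == 1 and log.n_excluded == 1

    def test_boundaries_inclusive(self, criteria):
        """Age 66 and 100, size exactly 50 mm, surgery at day 365 all qualify."""
        ok = [
            make_record(age_at_diagnosis=66.0),
            make_record(age_at_diagnosis=100.0),
            make_record(tumor_size_mm=50.0),
            make_record(surgeries=[("ablation", dt.date(2010, 1, 1) + dt.timedelta(days=365))]),
        ]
        subjects, log = apply_eligibility(ok, criteria)
        assert log.n_included == 4

    def test_first_failing_rule_wins(self, criteria):
        """A record violating several rules is logged only under the earliest."""
        rec = make_record(age_at_diagnosis=50.0, stage="other", enrollment_ok=False)
        _, log = apply_eligibility([rec], criteria)
        assert log.counts["enrollment"] == 1
        assert sum(log.counts.values()) == 1

    def test_toy_registry_attrition_matches_construction(self, criteria):
        """Hand-built registry: one record per rule violation plus three eligible."""
        violators = [
            make_record(id=1, age_at_diagnosis=64.0),
            make_record(id=2, enrollment_ok=False),
            make_record(id=3, stage=None),
            make_record(id=4, stage="other"),
            make_record(id=5, tumor_size_mm=80.0),
            make_record(id=6, surgeries=[]),
            make_record(id=7, surgeries=[("ablation", dt.date(2010, 5, 1)),
                                         ("hepatectomy", dt.date(2010, 5, 1))]),
        ]
        eligible = [make_record(id=8), make_record(id=9, married=1), make_record(id=10, stage="II")]
        subjects, log = apply_eligibility(violators + eligible, criteria)
        assert log.n_input == 10 and log.n_included == 3
        expected = {"age": 1, "enrollment": 1, "missing": 1, "stage": 1,
                    "tumor_size": 1, "surgery_window": 1, "same_day": 1}
        assert {k: v for k, v in log.counts.items() if v} == expected
        assert {s.id for s in subjects} == {8, 9, 10}

    def test_exclusion_log_order_invariant(self, criteria, rng):
        records = bt.generate_registry(bt.GeneratorConfig(n=300, seed=31, ineligible_fraction=0.4))
        _, log_a = apply_eligibility(records, criteria)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        _, log_b = apply_eligibility(shuffled, criteria)
        assert log_a.counts == log_b.counts

    def test_idempotent_on_eligible_cohort(self, criteria):
        records = bt.generate_registry(bt.GeneratorConfig(n=400, seed=37))
        subjects, log = apply_eligibility(records, criteria)
        assert log.n_included == len(records)
        kept = [r for r in records if r.id in {s.id for s in subjects}]
        subjects2, log2 = apply_eligibility(kept, criteria)
        assert log2.n_included == log.n_included
        assert [s.id for s in subjects2] == [s.id for s in subjects]

    def test_subgroup_is_subset_of_main(self):
        records = bt.generate_registry(bt.GeneratorConfig(n=600, seed=41))
        main, _ = apply_eligibility(records, bt.EligibilityCriteria(max_tumor_mm=50))
        sub, _ = apply_eligibility(records, bt.EligibilityCriteria(max_tumor_mm=30))
        assert {s.id for s in sub} <= {s.id for s in main}


class TestFollowup:
    def test_death_followup_years(self, criteria):
        rec = make_record(surgeries=[("ablation", dt.date(2010, 1, 1))],
                          death_date=dt.date(2015, 8, 14))
        t0, arm, fu, event, reason = define_followup(rec, criteria)
        expected = (dt.date(2015, 8, 14) - dt.date(2010, 1, 1)).days / DAYS_PER_YEAR
        assert fu == pytest.approx(expected) and round(fu, 2) == 5.62
        assert event == 1 and reason == "death" and arm == "ablation"

    def test_surgery_on_study_end(self, criteria):
        rec = make_record(diagnosis_date=dt.date(2019, 10, 1),
                          surgeries=[("ablation", dt.date(2019, 12, 31))])
        crit = bt.EligibilityCriteria(accrual_end=dt.date(2019, 12, 31))
        t0, _, fu, event, reason = define_followup(rec, crit)
        assert fu == 0.0 and event == 0 and reason == "admin_end"

    def test_crossover_censored_at_second_procedure_type(self, criteria):
        rec = make_record(
            diagnosis_date=dt.date(2011, 12, 1),
            surgeries=[("ablation", dt.date(2012, 1, 1)), ("hepatectomy", dt.date(2012, 6, 30))],
        )
        t0, arm, fu, event, reason = define_followup(rec, criteria)
        assert arm == "ablation" and t0 == dt.date(2012, 1, 1)
        assert reason == "second_procedure" and event == 0
        assert round(fu, 2) == 0.50

    def test_repeat_sessions_use_first_ablation(self, criteria):
        rec = make_record(surgeries=[("ablation", dt.date(2010, 3, 1)),
                                     ("ablation", dt.date(2010, 5, 1))])
        t0, arm, fu, event, reason = define_followup(rec, criteria)
        assert t0 == dt.date(2010, 3, 1) and reason == "admin_end"

    def test_death_before_surgery_is_corrupt(self, criteria):
        rec = make_record(death_date=dt.date(2010, 2, 1))  # surgery is 2010-03-01
        with pytest.raises(ValueError, match="death"):
            define_followup(rec, criteria)

    def test_event_iff_death_reason(self, criteria):
        records = bt.generate_registry(bt.GeneratorConfig(n=500, seed=43))
        subjects, _ = apply_eligibility(records, criteria)
        for s in subjects:
            assert (s.event == 1) == (s.censor_reason == "death")
            assert s.followup_years >= 0


class TestAnalysisFrame:
    def test_continuous_covariates_standardized(self, criteria):
        records = bt.generate_registry(bt.GeneratorConfig(n=800, seed=47))
        subjects, _ = apply_eligibility(records, criteria)
        frame, scaling = build_analysis_frame(subjects)
        for name in ("age", "tumor_size", "elixhauser"):
            assert frame[name].mean() == pytest.approx(0.0, abs=1e-10)
            assert frame[name].std(ddof=1) == pytest.approx(1.0, rel=1e-10)
            mean, sd = scaling[name]
            assert sd > 0
        assert set(np.unique(frame["arm"])) <= {0, 1}
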