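"""Rule-engine behaviour: plan generation, titration, ruleset validation."""

import copy

import numpy as np
import pytest
import yaml

from ncdcare import (
    PatientRecord,
    VisitMeasurements,
    generate_plan,
    load_ruleset,
    titrate,
    validate_ruleset,
)
from ncdcare.engine import (
    NoRuleFiredError,
    RuleConfigError,
    RuleSet,
    ladder_position,
)
from ncdcare.records import ValidationError


@pytest.fixture(scope="module")
def raw_config():
    import importlib.resources

    text = (
        importlib.resources.files("ncdcare") / "data" / "guideline_default.yaml"
    ).read_text()
    return yaml.safe_load(text)


PATIENT = PatientRecord("p1", 52, "female", "Kunihar", 0, "new", "none")


def bp_visit(sbp, dbp, month=0, meds=()):
    return VisitMeasurements(
        visit_month=month, sbp=sbp, dbp=dbp, current_medications=tuple(meds)
    )


class TestGeneratePlan:
    def test_prehypertension_gets_counseling_only(self, ruleset):
        plan = generate_plan(bp_visit(124, 82), PATIENT, ruleset)
        assert plan.drugs == ()
        assert "diet" in plan.counseling and "physical_activity" in plan.counseling
        assert not plan.referral

    def test_immediate_management_initiates_first_ladder_drug(self, ruleset):
        plan = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        assert plan.drugs == (("amlodipine", 2.5, "od"),)

    def test_screen_positive_band_initiates_treatment(self, ruleset):
        plan = generate_plan(bp_visit(150, 92), PATIENT, ruleset)
        assert len(plan.drugs) == 1

    @pytest.mark.parametrize("month", [0, 3, 12])
    def test_next_visit_is_three_months_on(self, ruleset, month):
        plan = generate_plan(bp_visit(150, 92, month=month), PATIENT, ruleset)
        assert plan.next_visit_month == month + 3

    def test_urgency_refers_without_new_drugs(self, ruleset):
        plan = generate_plan(bp_visit(195, 130), PATIENT, ruleset)
        assert plan.referral and plan.drugs == ()
        assert "urgency" in plan.referral_reason

    def test_determinism_byte_identical(self, ruleset):
        a = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        b = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        assert a == b
        assert a.render_card() == b.render_card()

    def test_out_of_domain_measurement_never_defaults(self, ruleset):
        with pytest.raises(NoRuleFiredError):
            generate_plan(bp_visit(300, 150), PATIENT, ruleset)

    def test_visit_without_covered_measurements_errors(self, ruleset):
        visit = VisitMeasurements(visit_month=0)
        with pytest.raises(NoRuleFiredError):
            generate_plan(visit, PATIENT, ruleset)

    def test_comorbid_plans_merge_both_rule_families(self, ruleset):
        visit = VisitMeasurements(
            visit_month=0, sbp=165, dbp=95, fpg=150, fasting_flag=True
        )
        plan = generate_plan(visit, PATIENT, ruleset)
        drugs = {d for d, _, _ in plan.drugs}
        assert drugs == {"amlodipine", "metformin"}

    def test_already_treated_patient_not_reinitiated(self, ruleset):
        visit = bp_visit(165, 95, meds=[("amlodipine", 5.0)])
        plan = generate_plan(visit, PATIENT, ruleset)
        assert plan.drugs == ()

    def test_every_plan_carries_ruleset_version(self, ruleset):
        plan = generate_plan(bp_visit(124, 82), PATIENT, ruleset)
        assert plan.ruleset_version == ruleset.version
        assert plan.ruleset_version in plan.render_card()


class TestTitration:
    def test_at_target_is_fixed_point(self, ruleset):
        start = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        follow = titrate(start, bp_visit(128, 82, month=3), ruleset)
        assert follow.drugs == start.drugs

    def test_above_target_advances_one_dose_step(self, ruleset):
        start = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        follow = titrate(start, bp_visit(150, 92, month=3), ruleset)
        assert follow.drugs == (("amlodipine", 5.0, "od"),)

    def test_max_dose_adds_next_ladder_drug(self, ruleset):
        plan = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        for month in (3, 6):  # 2.5 -> 5 -> 10
            plan = titrate(plan, bp_visit(160, 95, month=month), ruleset)
        assert plan.drugs == (("amlodipine", 10.0, "od"),)
        plan = titrate(plan, bp_visit(160, 95, month=9), ruleset)
        assert plan.drugs == (
            ("amlodipine", 10.0, "od"),
            ("enalapril", 2.5, "od"),
        )

    def test_never_skips_ladder_steps(self, ruleset):
        """Position advances by exactly one per above-target visit."""
        rules = ruleset.hypertension
        plan = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        pos = ladder_position([(d, dose) for d, dose, _ in plan.drugs], rules)
        for k, month in enumerate((3, 6, 9, 12, 15, 18)):
            plan = titrate(plan, bp_visit(170, 100, month=month), ruleset)
            new_pos = ladder_position(
                [(d, dose) for d, dose, _ in plan.drugs], rules
            )
            assert new_pos == pos + 1
            pos = new_pos

    def test_monotone_in_control_over_random_sweeps(self, ruleset):
        """Worse control never yields a lower ladder position than better
        control, all else equal (randomized visit-history sweep)."""
        rules = ruleset.hypertension
        rng = np.random.default_rng(42)
        months = (3, 6, 9, 12, 15, 18)
        for _ in range(50):
            above_a = rng.random(len(months)) < 0.5
            # history B is pointwise at-least-as-poorly-controlled as A
            above_b = above_a | (rng.random(len(months)) < 0.5)
            plans = {}
            for key, above in (("a", above_a), ("b", above_b)):
                plan = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
                for m, worse in zip(months, above):
                    visit = bp_visit(170, 100, month=m) if worse else bp_visit(
                        125, 80, month=m
                    )
                    plan = titrate(plan, visit, ruleset)
                plans[key] = ladder_position(
                    [(d, dose) for d, dose, _ in plan.drugs], rules
                )
            assert plans["b"] >= plans["a"]

    def test_exhausted_ladder_flags_physician_review(self, ruleset):
        plan = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        for i in range(15):
            plan = titrate(plan, bp_visit(170, 100, month=3), ruleset)
        assert any("physician review" in f for f in plan.flags)

    def test_unknown_previous_drug_is_config_error(self, ruleset):
        from dataclasses import replace

        plan = generate_plan(bp_visit(165, 95), PATIENT, ruleset)
        bad = replace(plan, drugs=(("reserpine", 0.1, "od"),))
        with pytest.raises(RuleConfigError, match="reserpine"):
            titrate(bad, bp_visit(170, 100, month=3), ruleset)

    def test_cannot_titrate_referred_plan(self, ruleset):
        plan = generate_plan(bp_visit(195, 130), PATIENT, ruleset)
        with pytest.raises(ValidationError):
            titrate(plan, bp_visit(150, 92, month=3), ruleset)


class TestRulesetValidation:
    def test_shipped_ruleset_has_no_gaps_or_overlaps(self, ruleset):
        report = validate_ruleset(ruleset)
        assert report.ok
        assert report.gaps == {} and report.overlaps == {}

    def test_overlapping_bands_reported(self, raw_config):
        cfg = copy.deepcopy(raw_config)
        cfg["hypertension"]["bands"]["sbp"] = [
            {"name": "normal", "lo": 60, "hi": 140},
            {"name": "stage1", "lo": 140, "hi": 161},
            {"name": "stage2", "lo": 150, "hi": 180},
            {"name": "urgency", "lo": 180, "hi": 260},
        ]
        report = validate_ruleset(RuleSet.model_validate(cfg))
        assert "hypertension.sbp" in report.overlaps
        assert 155 in report.overlaps["hypertension.sbp"]

    def test_band_gap_reported(self, raw_config):
        cfg = copy.deepcopy(raw_config)
        cfg["hypertension"]["bands"]["sbp"] = [
            {"name": "normal", "lo": 60, "hi": 140},
            {"name": "stage1", "lo": 140, "hi": 160},
            {"name": "stage2", "lo": 161, "hi": 180},  # [160, 161) uncovered
            {"name": "urgency", "lo": 180, "hi": 260},
        ]
        report = validate_ruleset(RuleSet.model_validate(cfg))
        assert report.gaps["hypertension.sbp"] == [160]

    def test_dangling_drug_reported(self, raw_config):
        cfg = copy.deepcopy(raw_config)
        cfg["diabetes"]["ladder"].append(
            {"drug": "insulin", "doses_mg": [10, 20], "frequency": "od"}
        )
        report = validate_ruleset(RuleSet.model_validate(cfg))
        assert "insulin" in report.dangling_drugs

    def test_unparseable_config_raises_with_location(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("version: [unclosed\n")
        with pytest.raises(RuleConfigError, match="parse"):
            load_ruleset(bad)
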