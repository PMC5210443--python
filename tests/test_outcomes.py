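"""Change-model estimation: oracle equivalence, coverage, missingness."""

import numpy as np
import pandas as pd
import pytest

from ncdcare import (
    CohortPanel,
    GeeSpec,
    SimConfig,
    describe_baseline,
    fit_change_model,
    missingness_profile,
    simulate_cohort,
)
from ncdcare.records import ValidationError
from ncdcare.simulate import diabetes_cohort_config, hypertension_cohort_config

from conftest import make_complete_panel, mean_difference_oracle

EFFECTS = {3: -12.9, 6: -17.0, 9: -16.1, 12: -15.9, 15: -16.6, 18: -14.6}


class TestOracleEquivalence:
    @pytest.mark.parametrize("corr", ["exchangeable", "unstructured"])
    def test_saturated_gee_equals_mean_differences(self, corr):
        """On complete balanced data the time-indicator GEE reproduces raw
        per-timepoint mean differences for any working correlation."""
        panel = make_complete_panel(120, EFFECTS, seed=3)
        oracle = mean_difference_oracle(panel, "sbp")
        table = fit_change_model(
            panel, GeeSpec(outcome="sbp", working_correlation=corr)
        )
        for m, truth in oracle.items():
            assert table.at(m)[0] == pytest.approx(truth, abs=1e-8)

    def test_zero_noise_recovers_effects_exactly(self):
        panel = make_complete_panel(30, {3: -10.0, 6: -12.0}, sd=0.0, seed=0)
        table = fit_change_model(panel, GeeSpec(outcome="sbp"))
        assert table.at(3)[0] == pytest.approx(-10.0, abs=1e-8)
        assert table.at(6)[0] == pytest.approx(-12.0, abs=1e-8)
        assert table.constant[0] == pytest.approx(146.0, abs=1e-8)

    def test_adjusted_equals_unadjusted_without_covariate_effects(self):
        """Cluster-constant covariates are orthogonal to time indicators on
        complete data, so adjustment must not move the change estimates."""
        panel = make_complete_panel(100, EFFECTS, seed=5)
        plain = fit_change_model(panel, GeeSpec(outcome="sbp"))
        adj = fit_change_model(
            panel, GeeSpec(outcome="sbp", covariates=("age", "sex", "site"))
        )
        for m in EFFECTS:
            assert adj.at(m)[0] == pytest.approx(plain.at(m)[0], abs=1e-8)

    def test_interaction_model_equals_stratified_mean_differences(self):
        panel = make_complete_panel(90, EFFECTS, seed=7)
        table = fit_change_model(
            panel, GeeSpec(outcome="sbp", interaction="new_vs_known")
        )
        for flag, label in ((True, "new"), (False, "known")):
            sub = CohortPanel(
                panel.df[panel.df["new_flag"] == flag].reset_index(drop=True)
            )
            oracle = mean_difference_oracle(sub, "sbp")
            for m, truth in oracle.items():
                assert table.at(m, label)[0] == pytest.approx(truth, abs=1e-8)


class TestRecoveryAndCoverage:
    def test_per_timepoint_ci_coverage_near_nominal(self):
        """True effects fall inside the 95% CI at ~95% across replicates."""
        reps, n = 120, 400
        config = hypertension_cohort_config(n=n)
        hits = total = 0
        for s in range(reps):
            panel = simulate_cohort(config, seed=1000 + s)
            table = fit_change_model(
                panel, GeeSpec(outcome="sbp", working_correlation="exchangeable")
            )
            for m, truth in EFFECTS.items():
                est, lo, hi = table.at(m)
                hits += lo <= truth <= hi
                total += 1
        coverage = hits / total
        se = np.sqrt(0.95 * 0.05 / total)
        assert coverage > 0.95 - 4 * se

    def test_sandwich_variance_tolerates_ar_noise(self):
        """Exchangeable working correlation fit on AR(1)-correlated noise:
        the robust CIs keep near-nominal coverage."""
        rng = np.random.default_rng(7)
        months = [0, 3, 6, 9, 12, 15, 18]
        n, reps, phi, sd = 300, 100, 0.7, 12.0
        hits = total = 0
        for _ in range(reps):
            rows = []
            for i in range(n):
                e = rng.normal(0, sd)
                for k, m in enumerate(months):
                    if k:
                        e = phi * e + rng.normal(0, sd * np.sqrt(1 - phi**2))
                    rows.append(
                        {
                            "patient_id": f"P{i}",
                            "site": "Syri",
                            "age": 50,
                            "sex": "female",
                            "new_flag": False,
                            "disease_group": "htn_only",
                            "visit_month": m,
                            "sbp": 146.0 + EFFECTS.get(m, 0.0) + e,
                            "dbp": 80.0 + 0.0,
                            "fpg": np.nan,
                            "fasting_flag": False,
                        }
                    )
            panel = CohortPanel(pd.DataFrame(rows))
            table = fit_change_model(
                panel, GeeSpec(outcome="sbp", working_correlation="exchangeable")
            )
            for m, truth in EFFECTS.items():
                _, lo, hi = table.at(m)
                hits += lo <= truth <= hi
                total += 1
        coverage = hits / total
        se = np.sqrt(0.95 * 0.05 / total)
        assert coverage > 0.95 - 4 * se

    def test_interaction_recovery_by_status(self):
        """Separate new/known generation profiles are recovered by the
        interaction parameterization."""
        config = diabetes_cohort_config(effects_by_status=True)
        panel = simulate_cohort(config, seed=3)
        table = fit_change_model(
            panel, GeeSpec(outcome="fpg", interaction="new_vs_known")
        )
        for label, truth18 in (("new", -58.57), ("known", -38.7)):
            est, lo, hi = table.at(18, label)
            se = (hi - lo) / (2 * 1.96)
            assert abs(est - truth18) < 3 * se


class TestDescriptives:
    def test_constant_outcome_zero_width_ci(self):
        panel = make_complete_panel(20, {3: 0.0}, sd=0.0, baseline=140.0)
        base = describe_baseline(panel, "sbp")
        row = base[base["group"] == "overall"].iloc[0]
        assert row["mean"] == pytest.approx(140.0)
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0, abs=1e-10)

    def test_two_value_mean(self):
        df = pd.DataFrame(
            [
                dict(patient_id=p, site="Syri", age=50, sex="male", new_flag=False,
                     disease_group="htn_only", visit_month=0, sbp=s, dbp=s - 60.0,
                     fpg=np.nan, fasting_flag=False)
                for p, s in (("a", 140.0), ("b", 150.0))
            ]
        )
        base = describe_baseline(CohortPanel(df), "sbp")
        assert base[base["group"] == "overall"]["mean"].iloc[0] == 145.0

    def test_baseline_mean_within_sampling_error_of_config(self):
        panel = simulate_cohort(hypertension_cohort_config(n=2000), seed=8)
        base = describe_baseline(panel, "sbp")
        row = base[base["group"] == "overall"].iloc[0]
        mix_mean = 0.52 * 149.1 + 0.48 * 143.0
        se = 15.83 / np.sqrt(row["n"])
        assert abs(row["mean"] - mix_mean) < 3 * se

    def test_scope_filters_disease_groups(self):
        panel = simulate_cohort(SimConfig(n_enrolled=800), seed=2)
        table = fit_change_model(panel, GeeSpec(outcome="fpg"))
        scoped = panel.patients()
        n_dm = scoped["disease_group"].isin(["dm_only", "both"]).sum()
        assert table.n == n_dm

    def test_empty_scope_errors(self):
        panel = simulate_cohort(hypertension_cohort_config(n=50), seed=0)
        with pytest.raises(ValidationError):
            fit_change_model(panel, GeeSpec(outcome="fpg"))


class TestMissingness:
    def test_complete_panel_has_equal_counts(self):
        panel = make_complete_panel(40, EFFECTS)
        prof = missingness_profile(panel)
        assert (prof["n_observed"] == 40).all()
        assert prof.attrs["monotone"]

    def test_censored_simulation_counts_non_increasing(self):
        panel = simulate_cohort(SimConfig(n_enrolled=2000), seed=5)
        prof = missingness_profile(panel)
        counts = prof.sort_values("visit_month")["n_observed"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        assert prof.attrs["monotone"]

    def test_constructed_gap_is_flagged(self):
        panel = make_complete_panel(5, {3: 0.0, 6: 0.0})
        df = panel.df[
            ~((panel.df["patient_id"] == "C00000") & (panel.df["visit_month"] == 3))
        ].reset_index(drop=True)
        prof = missingness_profile(CohortPanel(df))
        assert prof.attrs["intermittent_gap_patients"] == ["C00000"]
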