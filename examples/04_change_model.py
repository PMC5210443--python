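"""Fit the change-from-baseline GEE on a simulated hypertension cohort.

The model has one binary indicator per follow-up month, so each coefficient
is the mean change at that month relative to baseline.  The generating
truth here is the default change profile (-12.9 at 3 months, -14.6 at 18).
"""

from ncdcare import GeeSpec, describe_baseline, fit_change_model, simulate_cohort
from ncdcare.simulate import hypertension_cohort_config

panel = simulate_cohort(hypertension_cohort_config(n=3000), seed=7)

print("Baseline SBP (mm Hg):")
print(describe_baseline(panel, "sbp").to_string(
    index=False, float_format=lambda v: f"{v:.1f}"))
print()

table = fit_change_model(panel, GeeSpec(outcome="sbp"))
print("Change in SBP from baseline (unstructured working correlation):")
print(table.estimates.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()

adj = fit_change_model(
    panel, GeeSpec(outcome="sbp", covariates=("age", "sex", "site"))
)
est3, lo3, hi3 = adj.at(3)
print(f"age/sex/site-adjusted 3-month change: {est3:.2f} ({lo3:.2f}, {hi3:.2f})")

# The unadjusted 3-month estimate should sit near the generating -12.9 with
# its 95% CI covering it; adjustment barely moves the estimates because the
# generator gives the covariates no effect.
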