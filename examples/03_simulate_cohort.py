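"""Generate a synthetic screening-program cohort and look at its structure.

The default configuration reproduces the study conditions: 6797 enrolled
across 5 sites, disease mix 5281/781/735, staggered enrollment over 21
months with 3-monthly follow-up, so missingness is monotone by construction.
"""

from ncdcare import SimConfig, simulate_cohort, missingness_profile

panel = simulate_cohort(SimConfig(n_enrolled=2000), seed=42)
print(f"{panel.n_patients} patients, {len(panel)} visit rows")
print()
print("Disease mix (patients):")
print(panel.patients()["disease_group"].value_counts().to_string())
print()
print("Available N by visit month (administrative censoring only):")
prof = missingness_profile(panel)
print(prof.to_string(index=False))
print("monotone missingness:", prof.attrs["monotone"])

base = panel.df[panel.df["visit_month"] == 0]
print()
print(f"baseline SBP mean (hypertension scope): {base['sbp'].mean():.1f} mm Hg")
print(f"baseline FPG mean (diabetes scope):     {base['fpg'].mean():.1f} mg/dL")

# Counts shrink with follow-up month because later enrollees are censored by
# the program end — nobody re-appears after a missed visit.
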