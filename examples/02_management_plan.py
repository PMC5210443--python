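"""Plan generation and follow-up titration for one hypertensive patient.

A newly detected patient presents at 165/95 mm Hg; the engine initiates the
first drug of the ladder, then advances one ladder step per above-target
3-monthly visit and holds steady once the pressure is controlled.
"""

from ncdcare import PatientRecord, VisitMeasurements, generate_plan, load_ruleset, titrate

ruleset = load_ruleset()
patient = PatientRecord("HP-001", 58, "female", "Kunihar", 0, "new", "none")

visit0 = VisitMeasurements(0, sbp=165, dbp=95)
plan = generate_plan(visit0, patient, ruleset)
print(plan.render_card())
print()

followups = [(3, 158, 94), (6, 150, 92), (9, 132, 84), (12, 128, 82)]
for month, sbp, dbp in followups:
    plan = titrate(plan, VisitMeasurements(month, sbp=sbp, dbp=dbp), ruleset)
    regimen = ", ".join(f"{d} {dose:g}mg" for d, dose, _ in plan.drugs)
    print(f"month {month:2d}: BP {sbp}/{dbp} -> {regimen}")

# The dose climbs 2.5 -> 5 -> 10 mg while above target (>=140/90) and then
# stays fixed once the patient is controlled: one step per visit, never
# skipping, never auto-de-escalating.
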