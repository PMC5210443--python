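"""Opportunistic-screening triage: where one clinic attendee ends up.

Runs a handful of blood-pressure and glucose readings through the shipped
guideline rule set and prints the assigned screening group and action.
"""

from ncdcare import is_eligible, load_ruleset, triage_bp, triage_glucose

ruleset = load_ruleset()

print(f"Eligibility: age 29 -> {is_eligible(29)}, age 30 -> {is_eligible(30)}")
print()

cases = [
    ("BP 118/76, no history", lambda: triage_bp(118, 76, False, ruleset)),
    ("BP 128/84, no history", lambda: triage_bp(128, 84, False, ruleset)),
    ("BP 150/92, no history", lambda: triage_bp(150, 92, False, ruleset)),
    ("BP 165/95, no history", lambda: triage_bp(165, 95, False, ruleset)),
    ("BP 190/124, no history", lambda: triage_bp(190, 124, False, ruleset)),
    ("BP 150/92, known hypertension", lambda: triage_bp(150, 92, True, ruleset)),
    ("random glucose 210", lambda: triage_glucose(210, False, False, ruleset)),
    ("fasting glucose 130", lambda: triage_glucose(130, True, False, ruleset)),
    ("fasting glucose 110", lambda: triage_glucose(110, True, False, ruleset)),
]
for label, call in cases:
    out = call()
    extra = " (confirmed)" if out.confirmed else ""
    print(f"{label:32s} -> {out.group:16s} action={out.action}{extra}")

# Each reading lands in exactly one of the four screening groups; the action
# column is what the nurse care coordinator does next: recall the patient
# fasting, start management, refer upward, or counsel on lifestyle.
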