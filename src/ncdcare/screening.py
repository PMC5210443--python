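"""Opportunistic-screening triage for clinic attendees.

Every outpatient aged 30 or above is directed to the nurse care coordinator
for blood-pressure (and, where indicated, glucose) screening regardless of
presenting complaint.  Screening partitions attendees into four groups —
screen-positive hypertension, screen-positive diabetes, known/follow-up
cases, and screen-negative — with an action per group: confirmatory revisit,
immediate management (blood pressure above 160/100), referral to a
higher-level centre (hypertensive urgency/emergency), or lifestyle
counseling for the prehypertension/prediabetes bands.

:func:`tabulate_yield` produces the screening-yield accounting: per-site and
total counts of known vs newly detected cases by disease group, with the
eligible fraction and screen-positive yield.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .engine import RuleSet, _classify_bp
from .records import CohortPanel, ValidationError

ELIGIBILITY_AGE = 30

GROUPS = ("screen_pos_htn", "screen_pos_dm", "known_followup", "screen_negative")
ACTIONS = (
    "confirmatory_revisit",
    "immediate_management",
    "refer_higher_centre",
    "lifestyle_counseling",
    "none",
)


@dataclass(frozen=True)
class ScreeningOutcome:
    group: str
    action: str
    pre_state: str = "none"  # prehypertension | prediabetes | none
    confirmed: bool = False  # diagnosis confirmed at this encounter

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.action not in ACTIONS:
            raise ValidationError(f"unknown action {self.action!r}")
        if self.group == "screen_negative" and self.action not in (
            "lifestyle_counseling",
            "none",
        ):
            raise ValidationError(
                "screen-negative outcomes may only counsel or take no action"
            )
        if self.action == "immediate_management" and self.group != "screen_pos_htn":
            raise ValidationError(
                "immediate management applies only to screen-positive hypertension"
            )


def is_eligible(age: int) -> bool:
    """Eligible for opportunistic screening: aged 30 years or above."""
    if age < 0:
        raise ValidationError(f"age must be >= 0, got {age}")
    return age >= ELIGIBILITY_AGE


def triage_bp(
    sbp: float, dbp: float, known_htn: bool, ruleset: RuleSet
) -> ScreeningOutcome:
    """Classify a screening blood pressure into group + action.

    Known hypertension dominates every band: those patients are follow-up
    cases and approach the nurse care coordinator directly.  Otherwise the
    band (the more severe of the SBP and DBP arms) decides: urgency →
    referral; above 160/100 → immediate management; screen-positive band at
    or below 160/100 → confirmatory revisit; prehypertension → lifestyle
    counseling; normal → no action.
    """
    if not sbp > dbp > 0:
        raise ValidationError(f"require sbp > dbp > 0, got {sbp}/{dbp}")
    if known_htn:
        return ScreeningOutcome("known_followup", "none")
    rules = ruleset.hypertension
    band = _classify_bp(rules, sbp, dbp)
    if band == "urgency":
        return ScreeningOutcome("screen_pos_htn", "refer_higher_centre")
    if band == "stage2":
        return ScreeningOutcome("screen_pos_htn", "immediate_management")
    if band == "stage1":
        return ScreeningOutcome("screen_pos_htn", "confirmatory_revisit")
    if band == "prehypertension":
        return ScreeningOutcome(
            "screen_negative", "lifestyle_counseling", pre_state="prehypertension"
        )
    return ScreeningOutcome("screen_negative", "none")


def triage_glucose(
    glucose: float, fasting: bool, known_dm: bool, ruleset: RuleSet
) -> ScreeningOutcome:
    """Classify a screening glucose (mg/dL) into group + action.

    Non-fasting screen-positive values are recalled in fasting state for
    confirmatory laboratory diagnosis; a fasting value at or above the
    diagnostic cut confirms diabetes, the prediabetes band earns lifestyle
    counseling, and known diabetes dominates as a follow-up case.
    """
    if glucose <= 0:
        raise ValidationError(f"glucose must be positive, got {glucose}")
    if known_dm:
        return ScreeningOutcome("known_followup", "none")
    rules = ruleset.diabetes
    if not fasting:
        band = rules.classify_measure("random_glucose", glucose)
        if band == "screen_positive":
            return ScreeningOutcome("screen_pos_dm", "confirmatory_revisit")
        return ScreeningOutcome("screen_negative", "none")
    band = rules.classify_measure("fpg", glucose)
    if band == "diabetes":
        # Confirmed on a fasting sample: proceeds to plan generation.
        return ScreeningOutcome("screen_pos_dm", "none", confirmed=True)
    if band == "prediabetes":
        return ScreeningOutcome(
            "screen_negative", "lifestyle_counseling", pre_state="prediabetes"
        )
    return ScreeningOutcome("screen_negative", "none")


# ---------------------------------------------------------------------------
# Screening-yield accounting


_CELLS = (
    ("htn_only", False, "known_htn"),
    ("htn_only", True, "new_htn"),
    ("dm_only", False, "known_dm"),
    ("dm_only", True, "new_dm"),
    ("both", False, "known_both"),
    ("both", True, "new_both"),
)


@dataclass
class YieldTable:
    """Per-site and total screening-yield accounting.

    ``by_site`` has one row per site plus a ``Total`` row with columns
    ``attended, eligible, known_htn, new_htn, known_dm, new_dm, known_both,
    new_both, enrolled, pct_known, pct_new``.  Derived totals expose the
    quantities the program reports: eligible fraction among attendees,
    screen-positive yield among eligible, and the newly detected fraction
    within each disease.
    """

    by_site: pd.DataFrame

    @property
    def total(self) -> pd.Series:
        return self.by_site.loc["Total"]

    @property
    def eligible_pct(self) -> float:
        t = self.total
        return round(100.0 * t["eligible"] / t["attended"], 1)

    @property
    def screen_positive_pct(self) -> float:
        t = self.total
        return round(100.0 * t["enrolled"] / t["eligible"], 1)

    @property
    def new_htn_pct(self) -> float:
        t = self.total
        htn = t["known_htn"] + t["new_htn"] + t["known_both"] + t["new_both"]
        return round(100.0 * (t["new_htn"] + t["new_both"]) / htn, 1)

    @property
    def new_dm_pct(self) -> float:
        t = self.total
        dm = t["known_dm"] + t["new_dm"] + t["known_both"] + t["new_both"]
        return round(100.0 * (t["new_dm"] + t["new_both"]) / dm, 1)

    @property
    def comorbid_n(self) -> int:
        t = self.total
        return int(t["known_both"] + t["new_both"])

    def to_text(self) -> str:
        lines = [self.by_site.to_string()]
        lines.append("")
        lines.append(f"Eligible for screening: {self.eligible_pct}% of attendees")
        lines.append(
            f"Screen-positive yield: {self.screen_positive_pct}% of eligible"
        )
        lines.append(f"Newly detected among hypertension: {self.new_htn_pct}%")
        lines.append(f"Newly detected among diabetes: {self.new_dm_pct}%")
        lines.append(f"Comorbid (both conditions): N={self.comorbid_n}")
        return "\n".join(lines)


def tabulate_yield(
    panel: CohortPanel,
    clinic_attendance: Mapping[str, int],
    eligible_counts: Mapping[str, int],
) -> YieldTable:
    """Build the screening-yield table from an enrolled panel.

    ``clinic_attendance`` and ``eligible_counts`` give per-site outpatient
    attendance and the count aged 30+ (screening does not retain
    individual-level data on non-enrolled attendees, so these arrive as
    per-site totals).  Percentages are 100 x count / enrolled, rounded to one
    decimal; the table conserves counts — cells sum to the number of enrolled
    patients.
    """
    patients = panel.patients()
    sites = list(clinic_attendance)
    unknown_sites = set(patients["site"]) - set(sites)
    if unknown_sites:
        raise ValidationError(
            f"panel sites missing from attendance map: {sorted(unknown_sites)}"
        )
    missing_elig = set(sites) - set(eligible_counts)
    if missing_elig:
        raise ValidationError(
            f"sites missing from eligible-count map: {sorted(missing_elig)}"
        )

    rows = {}
    for site in sites:
        sub = patients[patients["site"] == site]
        row = {"attended": clinic_attendance[site], "eligible": eligible_counts[site]}
        for group, new, cell in _CELLS:
            row[cell] = int(
                ((sub["disease_group"] == group) & (sub["new_flag"] == new)).sum()
            )
        row["enrolled"] = len(sub)
        rows[site] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["Total"] = table.sum()
    enrolled = table["enrolled"].replace(0, pd.NA)
    known = table["known_htn"] + table["known_dm"] + table["known_both"]
    new = table["new_htn"] + table["new_dm"] + table["new_both"]
    table["pct_known"] = (100.0 * known / enrolled).astype(float).round(1)
    table["pct_new"] = (100.0 * new / enrolled).astype(float).round(1)
    return YieldTable(by_site=table)
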