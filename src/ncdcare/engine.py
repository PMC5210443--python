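"""The decision-support core: a generic evaluator for a declarative,
versioned clinical-management rule set.

Rules are data, not code.  A :class:`RuleSet` is loaded from a structured
YAML file that carries the measurement bands (as ordered half-open intervals
per measure), a plan template per band, per-drug titration ladders and the
formulary.  The engine evaluates the rule set over one visit's measurements
and produces a :class:`ManagementPlan` — drugs with doses, a referral flag,
counseling items and the next visit date — deterministically: identical
inputs always yield byte-identical plans, and every plan records the rule-set
version that produced it.

Follow-up titration advances exactly one ladder step per visit (dose up, or
the next drug at its first step once the current drug is at maximum dose),
mirroring a 3-monthly review cycle; at-target visits leave the regimen
unchanged and over-controlled patients are flagged for the physician rather
than automatically de-escalated.

:func:`validate_ruleset` is the machine analogue of scenario testing a
decision-support tool: it sweeps the full clinical measurement domain at
1-unit resolution and reports any value covered by zero bands (gap) or more
than one (overlap), plus dangling drug references and unreachable ladder
steps.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .records import PatientRecord, ValidationError, VisitMeasurements

FOLLOWUP_INTERVAL_MONTHS = 3


class RuleConfigError(ValueError):
    """The rule-set configuration is malformed or internally inconsistent."""


class NoRuleFiredError(ValueError):
    """A measurement fell outside every band's domain.

    Raised instead of ever emitting a silent default prescription.
    """


# ---------------------------------------------------------------------------
# Rule-set schema (pydantic: config files are schema-validated on load)


class Band(BaseModel):
    model_config = ConfigDict(frozen=True)
    name: str
    lo: float
    hi: float

    @field_validator("hi")
    @classmethod
    def _ordered(cls, v, info):
        if "lo" in info.data and v <= info.data["lo"]:
            raise ValueError("band must have hi > lo")
        return v

    def contains(self, x: float) -> bool:
        return self.lo <= x < self.hi


class LadderRung(BaseModel):
    model_config = ConfigDict(frozen=True)
    drug: str
    doses_mg: tuple[float, ...]
    frequency: str = "od"


class PlanTemplate(BaseModel):
    model_config = ConfigDict(frozen=True)
    drugs: Literal["initiate_none", "initiate_first"]
    counseling: tuple[str, ...] = ()
    referral: bool = False
    referral_reason: str = ""


class ConditionRules(BaseModel):
    model_config = ConfigDict(frozen=True)
    domain: dict[str, tuple[float, float]]
    severity_order: tuple[str, ...]
    bands: dict[str, tuple[Band, ...]]
    target: dict[str, float]
    plans: dict[str, PlanTemplate]
    ladder: tuple[LadderRung, ...]

    def classify_measure(self, measure: str, value: float) -> str:
        hits = [b.name for b in self.bands[measure] if b.contains(value)]
        if len(hits) != 1:
            raise NoRuleFiredError(
                f"{measure}={value}: {len(hits)} band(s) matched "
                f"(rule set must partition the domain)"
            )
        return hits[0]

    def severity(self, band_name: str) -> int:
        try:
            return self.severity_order.index(band_name)
        except ValueError:
            raise RuleConfigError(f"band {band_name!r} not in severity_order") from None


class RuleSet(BaseModel):
    """Versioned declarative encoding of the clinical-management guideline."""

    model_config = ConfigDict(frozen=True)
    version: str
    formulary: tuple[str, ...]
    precedence: tuple[str, ...]
    counseling_items: tuple[str, ...]
    hypertension: ConditionRules
    diabetes: ConditionRules


def load_ruleset(path: str | Path | None = None) -> RuleSet:
    """Load and schema-validate a rule-set YAML; default = shipped guideline."""
    if path is None:
        source = (
            importlib.resources.files("ncdcare") / "data" / "guideline_default.yaml"
        )
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # parse error with location, per contract
        raise RuleConfigError(f"cannot parse rule set: {exc}") from exc
    try:
        return RuleSet.model_validate(raw)
    except Exception as exc:
        raise RuleConfigError(f"rule set failed schema validation: {exc}") from exc


# ---------------------------------------------------------------------------
# Plans


@dataclass(frozen=True)
class ManagementPlan:
    """The engine's output for one visit.

    ``drugs`` is an ordered tuple of (drug, dose in mg, frequency).  A
    referred plan initiates no new drugs and keeps the patient with their
    current regimen until seen at the higher-level centre.
    """

    drugs: tuple[tuple[str, float, str], ...]
    referral: bool
    referral_reason: str
    counseling: tuple[str, ...]
    next_visit_month: int
    ruleset_version: str
    flags: tuple[str, ...] = ()

    def render_card(self) -> str:
        """Printable NCD-card text block handed to the patient."""
        lines = [f"NCD CARD (rule set v{self.ruleset_version})", "-" * 34]
        if self.referral:
            lines.append(f"REFER TO HIGHER CENTRE: {self.referral_reason}")
        if self.drugs:
            lines.append("Medications:")
            lines += [f"  - {d} {dose:g} mg {freq}" for d, dose, freq in self.drugs]
        else:
            lines.append("Medications: none")
        if self.counseling:
            lines.append("Counseling: " + ", ".join(self.counseling))
        for f in self.flags:
            lines.append(f"Note: {f}")
        lines.append(f"Next visit: month {self.next_visit_month}")
        return "\n".join(lines)


def _ladder_index(rules: ConditionRules) -> dict[str, int]:
    return {r.drug: i for i, r in enumerate(rules.ladder)}


def _first_step(rules: ConditionRules) -> tuple[str, float, str]:
    rung = rules.ladder[0]
    return (rung.drug, rung.doses_mg[0], rung.frequency)


def _classify_bp(rules: ConditionRules, sbp: float, dbp: float) -> str:
    """Combined blood-pressure band = the more severe of the two arms."""
    b_s = rules.classify_measure("sbp", sbp)
    b_d = rules.classify_measure("dbp", dbp)
    return max(b_s, b_d, key=rules.severity)


def _order_counseling(items: Iterable[str], ruleset: RuleSet) -> tuple[str, ...]:
    canon = {c: i for i, c in enumerate(ruleset.counseling_items)}
    return tuple(sorted(set(items), key=lambda c: canon.get(c, len(canon))))


def _condition_plan(
    rules: ConditionRules,
    band: str,
    on_treatment: bool,
) -> PlanTemplate:
    try:
        return rules.plans[band]
    except KeyError:
        raise RuleConfigError(f"no plan template for band {band!r}") from None


def generate_plan(
    visit: VisitMeasurements,
    patient: PatientRecord,
    ruleset: RuleSet,
) -> ManagementPlan:
    """Evaluate the rule set over one visit and emit an individualized plan.

    Exactly one band template fires per condition; comorbid patients are
    evaluated under both rule families and the plans merged (drug union with
    formulary-precedence ordering, counseling union, referral if either arm
    refers).  Deterministic: a pure function of its inputs.
    """
    drugs: list[tuple[str, float, str]] = []
    counseling: list[str] = []
    referral = False
    referral_reason = ""
    flags: list[str] = []
    current = {d for d, _ in visit.current_medications}

    evaluated = False
    if visit.sbp is not None and visit.dbp is not None:
        evaluated = True
        rules = ruleset.hypertension
        band = _classify_bp(rules, visit.sbp, visit.dbp)
        tpl = _condition_plan(rules, band, bool(current))
        if tpl.referral:
            referral = True
            referral_reason = tpl.referral_reason
        elif tpl.drugs == "initiate_first" and not (
            current & {r.drug for r in rules.ladder}
        ):
            drugs.append(_first_step(rules))
        counseling += tpl.counseling

    if visit.fpg is not None and visit.fasting_flag:
        evaluated = True
        rules = ruleset.diabetes
        band = rules.classify_measure("fpg", visit.fpg)
        tpl = _condition_plan(rules, band, bool(current))
        if tpl.referral:
            referral = True
            referral_reason = referral_reason or tpl.referral_reason
        elif tpl.drugs == "initiate_first" and not (
            current & {r.drug for r in rules.ladder}
        ):
            drugs.append(_first_step(rules))
        counseling += tpl.counseling

    if not evaluated:
        raise NoRuleFiredError("visit carries no measurements the rule set covers")

    if referral:
        drugs = []  # referred plans never initiate new drugs
    prec = {d: i for i, d in enumerate(ruleset.precedence)}
    drugs.sort(key=lambda t: prec.get(t[0], len(prec)))
    return ManagementPlan(
        drugs=tuple(drugs),
        referral=referral,
        referral_reason=referral_reason,
        counseling=_order_counseling(counseling, ruleset),
        next_visit_month=visit.visit_month + FOLLOWUP_INTERVAL_MONTHS,
        ruleset_version=ruleset.version,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Titration


def ladder_position(
    regimen: Iterable[tuple[str, float]], rules: ConditionRules
) -> int:
    """Total ladder steps represented by a regimen (0 = untreated).

    Each (drug, dose) contributes 1 + the index of the dose within the
    drug's dose steps.
    """
    pos = 0
    by_drug = {r.drug: r for r in rules.ladder}
    for drug, dose in regimen:
        if drug not in by_drug:
            raise RuleConfigError(f"drug {drug!r} not in titration ladder")
        steps = by_drug[drug].doses_mg
        if dose not in steps:
            raise RuleConfigError(f"dose {dose} of {drug!r} not a ladder step {steps}")
        pos += 1 + steps.index(dose)
    return pos


def _escalate(
    regimen: list[tuple[str, float]], rules: ConditionRules
) -> tuple[list[tuple[str, float]], str | None]:
    """Advance one ladder step; returns (new regimen, flag-or-None)."""
    by_drug = {r.drug: r for r in rules.ladder}
    order = _ladder_index(rules)
    if not regimen:
        rung = rules.ladder[0]
        return [(rung.drug, rung.doses_mg[0])], None
    regimen = sorted(regimen, key=lambda t: order.get(t[0], len(order)))
    # Dose-up the highest-order drug not yet at max dose.
    for i in range(len(regimen) - 1, -1, -1):
        drug, dose = regimen[i]
        steps = by_drug[drug].doses_mg
        k = steps.index(dose)
        if k + 1 < len(steps):
            regimen[i] = (drug, steps[k + 1])
            return regimen, None
    # All current drugs at max: add the next drug in the ladder.
    have = {d for d, _ in regimen}
    for rung in rules.ladder:
        if rung.drug not in have:
            regimen.append((rung.drug, rung.doses_mg[0]))
            return regimen, None
    return regimen, "maximal ladder therapy reached; physician review advised"


def _above_target(rules: ConditionRules, visit: VisitMeasurements) -> bool | None:
    t = rules.target
    if "sbp_below" in t:
        if visit.sbp is None:
            return None
        return visit.sbp >= t["sbp_below"] or visit.dbp >= t["dbp_below"]
    if visit.fpg is None or not visit.fasting_flag:
        return None
    return visit.fpg >= t["fpg_below"]


def titrate(
    previous_plan: ManagementPlan,
    visit: VisitMeasurements,
    ruleset: RuleSet,
) -> ManagementPlan:
    """Follow-up dose adjustment: one ladder step per 3-monthly visit.

    Above-target measurements advance the relevant condition's regimen by
    exactly one step — the current drug's next dose, or the next ladder drug
    at its first step once the current drug is at maximum.  At-target visits
    are a fixed point (regimen unchanged); no automatic de-escalation.
    """
    if previous_plan.referral:
        raise ValidationError("cannot titrate a referred plan")
    if visit.visit_month < FOLLOWUP_INTERVAL_MONTHS:
        raise ValidationError("titration applies to follow-up visits only")

    freq = {r.drug: r.frequency for cond in (ruleset.hypertension, ruleset.diabetes)
            for r in cond.ladder}
    flags: list[str] = []
    counseling: list[str] = list(previous_plan.counseling)
    new_regimen: list[tuple[str, float]] = []
    prev = [(d, dose) for d, dose, _ in previous_plan.drugs]

    for rules in (ruleset.hypertension, ruleset.diabetes):
        ladder_drugs = {r.drug for r in rules.ladder}
        arm = [(d, dose) for d, dose in prev if d in ladder_drugs]
        for d, _ in arm:  # contract: previous drugs must exist in the ladder
            ladder_position([(d, dict(arm)[d])], rules)
        above = _above_target(rules, visit)
        if above is None:
            new_regimen += arm
            continue
        if above:
            arm, flag = _escalate(arm, rules)
            if flag:
                flags.append(flag)
            counseling += [
                "diet", "tobacco_cessation", "physical_activity",
                "alcohol_moderation", "drug_compliance",
            ]
        new_regimen += arm

    unknown = {d for d, _ in prev} - {
        r.drug for cond in (ruleset.hypertension, ruleset.diabetes)
        for r in cond.ladder
    }
    if unknown:
        raise RuleConfigError(f"previous drugs not in any ladder: {sorted(unknown)}")

    prec = {d: i for i, d in enumerate(ruleset.precedence)}
    new_regimen.sort(key=lambda t: prec.get(t[0], len(prec)))
    return ManagementPlan(
        drugs=tuple((d, dose, freq[d]) for d, dose in new_regimen),
        referral=False,
        referral_reason="",
        counseling=_order_counseling(counseling, ruleset),
        next_visit_month=visit.visit_month + FOLLOWUP_INTERVAL_MONTHS,
        ruleset_version=ruleset.version,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Rule-set validation


@dataclass
class RulesetReport:
    """Outcome of exhaustive-grid scenario validation of a rule set."""

    gaps: dict[str, list[float]] = field(default_factory=dict)
    overlaps: dict[str, list[float]] = field(default_factory=dict)
    dangling_drugs: list[str] = field(default_factory=list)
    unreachable_steps: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.gaps or self.overlaps or self.dangling_drugs or self.unreachable_steps
        )


def validate_ruleset(ruleset: RuleSet, resolution: float = 1.0) -> RulesetReport:
    """Exhaustively scenario-test a rule set over its measurement domain.

    Sweeps every measure's domain at ``resolution`` (default 1 unit — the
    clinical measurement grid) and records values matched by no band (gap)
    or several (overlap); also reports ladder drugs missing from the
    formulary and ladder steps that one-step escalation can never reach
    (non-increasing dose sequences).
    """
    report = RulesetReport()
    for cond_name, rules in (
        ("hypertension", ruleset.hypertension),
        ("diabetes", ruleset.diabetes),
    ):
        for measure, (lo, hi) in rules.domain.items():
            x = lo
            gaps, overlaps = [], []
            while x < hi:
                n = sum(b.contains(x) for b in rules.bands[measure])
                if n == 0:
                    gaps.append(x)
                elif n > 1:
                    overlaps.append(x)
                x += resolution
            key = f"{cond_name}.{measure}"
            if gaps:
                report.gaps[key] = gaps
            if overlaps:
                report.overlaps[key] = overlaps
        for rung in rules.ladder:
            if rung.drug not in ruleset.formulary:
                report.dangling_drugs.append(rung.drug)
            for a, b in zip(rung.doses_mg, rung.doses_mg[1:]):
                if b <= a:
                    report.unreachable_steps.append(
                        f"{rung.drug}: dose step {b} not above {a}"
                    )
        for band_name in rules.plans:
            if band_name not in rules.severity_order:
                report.unreachable_steps.append(
                    f"{cond_name}: plan template {band_name!r} matches no band"
                )
    return report
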