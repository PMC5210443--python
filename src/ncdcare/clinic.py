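"""Clinic visit state machine and physician-agreement accounting.

One encounter walks a fixed station order: registration → nurse screening
(for eligible walk-ins) → decision-support plan generation → physician
review → counseling → exit.  The physician either approves the generated
plan or modifies/rejects it, recording a reason for disagreement on the NCD
card; physician behaviour is injected as a policy callable so the workflow
is testable without humans.

:func:`agreement_rate` reproduces the program's prescription audit: the
first N consecutive episodes per site, pooled approved-fraction plus a
disagreement-reason histogram.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np

from .engine import ManagementPlan, RuleSet, generate_plan
from .records import PatientRecord, ValidationError, VisitMeasurements
from .screening import is_eligible

STATE_ORDER = (
    "registration",
    "ncc_screening",
    "mdss_plan",
    "physician_review",
    "counseling",
    "exit",
)

DECISIONS = ("approved", "modified", "rejected")


class StateMachineError(RuntimeError):
    """A visit was routed through stations in an impossible order."""


@dataclass(frozen=True)
class VisitEpisode:
    """One completed walk through the clinic workflow."""

    patient_id: str
    site: str
    seq: int  # visit timestamp order within site (audit uses "consecutive")
    states: tuple[str, ...]
    mdss_plan: ManagementPlan
    physician_decision: str
    disagreement_reason: str
    final_plan: ManagementPlan

    def __post_init__(self) -> None:
        order = {s: i for i, s in enumerate(STATE_ORDER)}
        unknown = [s for s in self.states if s not in order]
        if unknown:
            raise StateMachineError(f"unknown states {unknown}")
        idx = [order[s] for s in self.states]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise StateMachineError(
                f"states must follow the workflow order, got {self.states}"
            )
        for required in ("mdss_plan", "physician_review", "exit"):
            if required not in self.states:
                raise StateMachineError(f"episode missing state {required!r}")
        if self.physician_decision not in DECISIONS:
            raise ValidationError(
                f"decision must be one of {DECISIONS}, got {self.physician_decision!r}"
            )
        if (self.physician_decision != "approved") != bool(self.disagreement_reason):
            raise ValidationError(
                "disagreement_reason must be non-empty iff the plan was not approved"
            )

    @property
    def approved(self) -> bool:
        return self.physician_decision == "approved"


#: Physician policy contract: (plan, visit) -> (decision, reason-or-"").
PhysicianPolicy = Callable[[ManagementPlan, VisitMeasurements], tuple[str, str]]


def always_approve(plan: ManagementPlan, visit: VisitMeasurements) -> tuple[str, str]:
    return "approved", ""


def always_reject(
    reason: str = "medicine unavailable at CHC pharmacy",
) -> PhysicianPolicy:
    def policy(plan: ManagementPlan, visit: VisitMeasurements) -> tuple[str, str]:
        return "rejected", reason

    return policy


def bernoulli_policy(
    p_approve: float,
    rng: np.random.Generator,
    reason: str = "medicine unavailable at CHC pharmacy",
) -> PhysicianPolicy:
    """Approve with probability ``p_approve``, otherwise modify with a reason."""
    if not 0.0 <= p_approve <= 1.0:
        raise ValidationError(f"p_approve must be in [0, 1], got {p_approve}")

    def policy(plan: ManagementPlan, visit: VisitMeasurements) -> tuple[str, str]:
        if rng.random() < p_approve:
            return "approved", ""
        return "modified", reason

    return policy


def threshold_disagree(
    max_drugs: int = 2, reason: str = "regimen simplified by physician"
) -> PhysicianPolicy:
    """Modify any plan carrying more than ``max_drugs`` drugs."""

    def policy(plan: ManagementPlan, visit: VisitMeasurements) -> tuple[str, str]:
        if len(plan.drugs) > max_drugs:
            return "modified", reason
        return "approved", ""

    return policy


def run_episode(
    patient: PatientRecord,
    visit: VisitMeasurements,
    ruleset: RuleSet,
    physician_policy: PhysicianPolicy,
    seq: int = 0,
) -> VisitEpisode:
    """Run one patient visit through the clinic workflow.

    Screening is traversed only at a first (baseline) visit by an eligible
    walk-in; known/follow-up cases approach the nurse care coordinator
    directly.  The final plan equals the generated plan iff the physician
    approved it; a modified/rejected plan keeps the patient's current regimen
    and the physician's documented reason travels on the episode.
    """
    states = ["registration"]
    if visit.visit_month == 0 and patient.htn_status != "known" and (
        patient.dm_status != "known"
    ):
        if not is_eligible(patient.age):
            raise StateMachineError(
                f"patient {patient.patient_id} (age {patient.age}) routed to "
                "screening but is not eligible"
            )
        states.append("ncc_screening")
    plan = generate_plan(visit, patient, ruleset)
    states.append("mdss_plan")
    decision, reason = physician_policy(plan, visit)
    states.append("physician_review")
    if decision == "approved":
        final = plan
    else:
        # Physician overrode the suggestion: keep current regimen, retain
        # counseling and follow-up schedule.
        final = replace(plan, drugs=tuple(
            (d, dose, "od") for d, dose in visit.current_medications
        ))
    states.append("counseling")  # counseling precedes exit for enrolled patients
    states.append("exit")
    return VisitEpisode(
        patient_id=patient.patient_id,
        site=patient.site,
        seq=seq,
        states=tuple(states),
        mdss_plan=plan,
        physician_decision=decision,
        disagreement_reason=reason,
        final_plan=final,
    )


@dataclass
class AgreementReport:
    rate: float
    n: int
    by_reason: Counter = field(default_factory=Counter)

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def agreement_rate(
    episodes: Iterable[VisitEpisode], sample_per_site: int
) -> AgreementReport:
    """Prescription-audit agreement: first N consecutive episodes per site.

    Takes the first ``sample_per_site`` episodes per site in visit order
    (``seq``), pools them across sites, and returns the approved fraction
    with a histogram of disagreement reasons.  Errors if any site cannot
    contribute the full sample.
    """
    by_site: dict[str, list[VisitEpisode]] = {}
    for ep in episodes:
        by_site.setdefault(ep.site, []).append(ep)
    sampled: list[VisitEpisode] = []
    for site, eps in by_site.items():
        eps = sorted(eps, key=lambda e: e.seq)
        if len(eps) < sample_per_site:
            raise ValidationError(
                f"site {site!r} has only {len(eps)} episodes; "
                f"{sample_per_site} required"
            )
        sampled += eps[:sample_per_site]
    if not sampled:
        raise ValidationError("no episodes supplied")
    approved = sum(ep.approved for ep in sampled)
    reasons = Counter(
        ep.disagreement_reason for ep in sampled if not ep.approved
    )
    return AgreementReport(
        rate=approved / len(sampled), n=len(sampled), by_reason=reasons
    )
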