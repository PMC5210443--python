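"""Synthetic-cohort generator matching the program's enrollment structure.

The generator emulates a 21-month continuous-enrollment program at 5 rural
community health centres: 6797 enrolled patients split 5281 / 781 / 735
across hypertension-only, diabetes-only and comorbid groups, roughly half
newly detected by opportunistic screening (52% of hypertension, 30% of
diabetes).  Outcomes follow a marginal means model

    y_it = mu(group, status) + delta_status(t) + u_i + e_it

where ``delta(t)`` is the true per-timepoint change profile (defaults: the
program's observed unadjusted change columns), and ``u_i + e_it`` is
zero-mean Gaussian noise with exchangeable within-person correlation rho
(variance split u ~ rho*sd^2, e ~ (1-rho)*sd^2, so the marginal variance is
sd^2 and every pair of visits correlates at rho).

Baseline standard deviations are not reported directly; they are recovered
by inverting the printed 95% confidence intervals of the baseline means
(sd = half-width * sqrt(n) / 1.96), computed at config construction.

Follow-up is 3-monthly; a patient enrolled in calendar month ``e`` (uniform
over the window) is observed at follow-up month ``m`` iff ``e + m`` falls
before the program end, giving administrative censoring only and hence
monotone missingness by construction.  An optional attrition hazard is
provided for sensitivity work but defaults to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .records import CohortPanel

Z975 = 1.959963984540054

# Per-site accounting of the screening program (attendance, aged 30+,
# enrolled) used for site weights and the screening-stream defaults.
SITES = ("Kunihar", "Syri", "Dharampur", "Dharlagarh", "Nalagarh")
SITE_ATTENDANCE: dict[str, int] = {
    "Kunihar": 34633,
    "Syri": 12494,
    "Dharampur": 28564,
    "Dharlagarh": 22649,
    "Nalagarh": 34030,
}
SITE_ELIGIBLE: dict[str, int] = {
    "Kunihar": 4984,
    "Syri": 1824,
    "Dharampur": 3847,
    "Dharlagarh": 3533,
    "Nalagarh": 7821,
}
SITE_ENROLLED: dict[str, int] = {
    "Kunihar": 1625,
    "Syri": 588,
    "Dharampur": 1092,
    "Dharlagarh": 851,
    "Nalagarh": 2641,
}

N_ENROLLED = 6797
N_HTN = 6016
N_DM = 1516
DISEASE_COUNTS = {"htn_only": 5281, "dm_only": 781, "both": 735}

# True change profiles (mm Hg / mg/dL relative to baseline) — the observed
# unadjusted and by-status change columns of the program evaluation.
SBP_CHANGE_OVERALL = {3: -12.9, 6: -17.0, 9: -16.1, 12: -15.9, 15: -16.6, 18: -14.6}
SBP_CHANGE_NEW = {3: -15.3, 6: -20.2, 9: -19.4, 12: -19.5, 15: -19.7, 18: -18.6}
SBP_CHANGE_KNOWN = {3: -11.3, 6: -14.6, 9: -13.4, 12: -13.3, 15: -14.5, 18: -14.3}
DBP_CHANGE_OVERALL = {3: -7.1, 6: -8.1, 9: -7.7, 12: -8.4, 15: -8.4, 18: -7.7}
DBP_CHANGE_NEW = {3: -8.9, 6: -10.2, 9: -10.1, 12: -10.2, 15: -10.1, 18: -10.0}
DBP_CHANGE_KNOWN = {3: -4.9, 6: -5.7, 9: -4.9, 12: -6.1, 15: -6.2, 18: -5.8}
FPG_CHANGE_OVERALL = {3: -31.5, 6: -42.5, 9: -44.6, 12: -49.3, 15: -46.8, 18: -50.2}
FPG_CHANGE_NEW = {3: -36.1, 6: -51.9, 9: -57.4, 12: -57.5, 15: -57.2, 18: -58.57}
FPG_CHANGE_KNOWN = {3: -24.0, 6: -32.4, 9: -32.4, 12: -39.0, 15: -34.9, 18: -38.7}


def sd_from_ci(half_width: float, n: int) -> float:
    """Invert a normal-approximation 95% CI half-width to a standard deviation."""
    return half_width * math.sqrt(n) / Z975


@dataclass(frozen=True)
class OutcomeSpec:
    """Marginal distribution + true change profile for one outcome."""

    mean_new: float
    mean_known: float
    sd: float
    changes: Mapping[int, float]
    changes_new: Mapping[int, float] | None = None
    changes_known: Mapping[int, float] | None = None

    def mean(self, new: bool) -> float:
        return self.mean_new if new else self.mean_known

    def change(self, month: int, new: bool, by_status: bool) -> float:
        if month == 0:
            return 0.0
        if by_status:
            prof = self.changes_new if new else self.changes_known
            if prof is None:
                raise ValueError("by-status profiles not configured")
            return prof[month]
        return self.changes[month]


def default_sbp_spec() -> OutcomeSpec:
    return OutcomeSpec(
        mean_new=149.1,
        mean_known=143.0,
        sd=sd_from_ci(0.4, N_HTN),
        changes=SBP_CHANGE_OVERALL,
        changes_new=SBP_CHANGE_NEW,
        changes_known=SBP_CHANGE_KNOWN,
    )


def default_dbp_spec() -> OutcomeSpec:
    # By-status baseline DBP means are not reported; both statuses share the
    # overall baseline mean.
    return OutcomeSpec(
        mean_new=89.52,
        mean_known=89.52,
        sd=sd_from_ci((89.72 - 89.33) / 2, N_HTN),
        changes=DBP_CHANGE_OVERALL,
        changes_new=DBP_CHANGE_NEW,
        changes_known=DBP_CHANGE_KNOWN,
    )


def default_fpg_spec() -> OutcomeSpec:
    return OutcomeSpec(
        mean_new=185.1,
        mean_known=174.8,
        sd=sd_from_ci(2.1, N_DM),
        changes=FPG_CHANGE_OVERALL,
        changes_new=FPG_CHANGE_NEW,
        changes_known=FPG_CHANGE_KNOWN,
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-conditions configuration of the cohort generator.

    Defaults reproduce the program's enrollment structure; proportions must
    sum to 1 and standard deviations be positive.  ``effects_by_status``
    switches the true change profile from the overall column to separate
    new/known columns (for interaction-model recovery work).
    """

    n_enrolled: int = N_ENROLLED
    site_weights: Mapping[str, float] = field(
        default_factory=lambda: {s: n / N_ENROLLED for s, n in SITE_ENROLLED.items()}
    )
    disease_mix: Mapping[str, float] = field(
        default_factory=lambda: {g: n / N_ENROLLED for g, n in DISEASE_COUNTS.items()}
    )
    new_fraction_htn: float = 0.52
    new_fraction_dm: float = 0.30
    sbp: OutcomeSpec = field(default_factory=default_sbp_spec)
    dbp: OutcomeSpec = field(default_factory=default_dbp_spec)
    fpg: OutcomeSpec = field(default_factory=default_fpg_spec)
    rho: float = 0.5
    noise_scale: float = 1.0
    effects_by_status: bool = False
    enrollment_window_months: int = 21
    followup_months: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18)
    attrition_hazard: float = 0.0
    # Covariate effects on every outcome (defaults 0, so adjusted and
    # unadjusted analyses coincide unless deliberately switched on).
    site_effects: Mapping[str, float] = field(default_factory=dict)
    age_coef: float = 0.0
    male_effect: float = 0.0

    def __post_init__(self) -> None:
        for name in ("site_weights", "disease_mix"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total!r}")
        for spec in (self.sbp, self.dbp, self.fpg):
            if spec.sd <= 0:
                raise ValueError("outcome sds must be positive")
            for m in self.followup_months:
                if m:
                    spec.change(m, True, self.effects_by_status)
                    spec.change(m, False, self.effects_by_status)
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 <= self.attrition_hazard < 1.0:
            raise ValueError("attrition_hazard must be in [0, 1)")


def hypertension_cohort_config(n: int = N_HTN, **overrides) -> SimConfig:
    """All-hypertension cohort (the scope of the blood-pressure analyses)."""
    return SimConfig(
        n_enrolled=n,
        disease_mix={"htn_only": 1.0, "dm_only": 0.0, "both": 0.0},
        **overrides,
    )


def diabetes_cohort_config(n: int = N_DM, **overrides) -> SimConfig:
    """All-diabetes cohort (the scope of the fasting-glucose analyses)."""
    return SimConfig(
        n_enrolled=n,
        disease_mix={"htn_only": 0.0, "dm_only": 1.0, "both": 0.0},
        **overrides,
    )


def _observed_months(
    config: SimConfig, enroll_month: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Visit months observed per patient: administrative censoring (+ optional
    attrition), hence a contiguous prefix of the follow-up grid."""
    end = config.enrollment_window_months - 1
    months = np.asarray(config.followup_months)
    out = []
    for e in enroll_month:
        obs = months[e + months <= end]
        if config.attrition_hazard > 0 and len(obs) > 1:
            # geometric attrition: stop at first dropout, keeping monotonicity
            keep = 1
            while keep < len(obs) and rng.random() >= config.attrition_hazard:
                keep += 1
            obs = obs[:keep]
        out.append(obs)
    return out


def simulate_cohort(config: SimConfig | None = None, seed: int = 0) -> CohortPanel:
    """Draw one synthetic cohort panel under the configured study conditions.

    Reproducible: identical (config, seed) yield identical panels.  Blood
    pressure is generated for patients with hypertension (alone or comorbid),
    fasting glucose for patients with diabetes; the panel's missingness is
    monotone by construction.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    n = config.n_enrolled

    sites = rng.choice(
        list(config.site_weights), p=list(config.site_weights.values()), size=n
    )
    groups = rng.choice(
        list(config.disease_mix), p=list(config.disease_mix.values()), size=n
    )
    ages = np.clip(rng.normal(57.0, 11.0, size=n).round().astype(int), 30, 90)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    p_new = np.where(groups == "dm_only", config.new_fraction_dm,
                     config.new_fraction_htn)
    new_flags = rng.random(n) < p_new
    enroll = rng.integers(0, config.enrollment_window_months, size=n)
    observed = _observed_months(config, enroll, rng)

    has_htn = np.isin(groups, ("htn_only", "both"))
    has_dm = np.isin(groups, ("dm_only", "both"))

    def person_effect(spec: OutcomeSpec) -> np.ndarray:
        return rng.normal(
            0.0, config.noise_scale * spec.sd * math.sqrt(config.rho), size=n
        )

    u = {name: person_effect(spec) for name, spec in
         (("sbp", config.sbp), ("dbp", config.dbp), ("fpg", config.fpg))}

    rows = []
    for i in range(n):
        pid = f"P{i:05d}"
        for m in observed[i]:
            row = {
                "patient_id": pid,
                "site": sites[i],
                "age": int(ages[i]),
                "sex": sexes[i],
                "new_flag": bool(new_flags[i]),
                "disease_group": groups[i],
                "visit_month": int(m),
                "sbp": np.nan,
                "dbp": np.nan,
                "fpg": np.nan,
                "fasting_flag": False,
            }
            covar = (
                config.site_effects.get(sites[i], 0.0)
                + config.age_coef * (ages[i] - 57.0)
                + (config.male_effect if sexes[i] == "male" else 0.0)
            )
            if has_htn[i]:
                for name, spec in (("sbp", config.sbp), ("dbp", config.dbp)):
                    e = rng.normal(
                        0.0,
                        config.noise_scale * spec.sd * math.sqrt(1 - config.rho),
                    )
                    row[name] = (
                        spec.mean(new_flags[i])
                        + spec.change(int(m), new_flags[i], config.effects_by_status)
                        + covar + u[name][i] + e
                    )
                # physiological floor on pulse pressure: SBP and DBP noise is
                # drawn independently, so rare tail draws would cross
                row["dbp"] = min(row["dbp"], row["sbp"] - 10.0)
            if has_dm[i]:
                spec = config.fpg
                e = rng.normal(
                    0.0, config.noise_scale * spec.sd * math.sqrt(1 - config.rho)
                )
                # floor at severe hypoglycemia: glucose is positive by nature
                row["fpg"] = max(
                    spec.mean(new_flags[i])
                    + spec.change(int(m), new_flags[i], config.effects_by_status)
                    + covar + u["fpg"][i] + e,
                    30.0,
                )
                row["fasting_flag"] = True
            rows.append(row)

    df = pd.DataFrame(rows)
    panel = CohortPanel(df, meta={"seed": seed, "n_enrolled": n})
    return panel


# ---------------------------------------------------------------------------
# Screening stream


@dataclass(frozen=True)
class ScreeningStreamConfig:
    """Clinic attendance and screening-yield fractions for the visit stream."""

    attendance: Mapping[str, int] = field(
        default_factory=lambda: dict(SITE_ATTENDANCE)
    )
    eligible_fraction: float = 22009 / 132370  # aged 30+ among attendees
    screen_positive_yield: float = 6797 / 22009  # enrolled among eligible
    disease_mix: Mapping[str, float] = field(
        default_factory=lambda: {g: n / N_ENROLLED for g, n in DISEASE_COUNTS.items()}
    )
    new_fraction_htn: float = 0.52
    new_fraction_dm: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 <= self.eligible_fraction <= 1.0:
            raise ValueError("eligible_fraction must be in [0, 1]")
        if not 0.0 <= self.screen_positive_yield <= 1.0:
            raise ValueError("screen_positive_yield must be in [0, 1]")


def simulate_screening_stream(
    config: ScreeningStreamConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Emit one attendee per row: site, age, eligibility and screening result.

    Ages are drawn so the expected eligible (30+) fraction matches the
    configured value; disease among the eligible matches the configured
    screen-positive yield and disease mix.
    """
    config = config or ScreeningStreamConfig()
    rng = np.random.default_rng(seed)
    frames = []
    for site, n_att in config.attendance.items():
        eligible = rng.random(n_att) < config.eligible_fraction
        ages = np.where(
            eligible, rng.integers(30, 85, size=n_att), rng.integers(5, 30, size=n_att)
        )
        enrolled = eligible & (rng.random(n_att) < config.screen_positive_yield)
        groups = np.where(
            enrolled,
            rng.choice(
                list(config.disease_mix),
                p=list(config.disease_mix.values()),
                size=n_att,
            ),
            "none",
        )
        p_new = np.where(
            groups == "dm_only", config.new_fraction_dm, config.new_fraction_htn
        )
        new_flags = enrolled & (rng.random(n_att) < p_new)
        frames.append(
            pd.DataFrame(
                {
                    "site": site,
                    "age": ages,
                    "eligible": eligible,
                    "enrolled": enrolled,
                    "disease_group": groups,
                    "new_flag": new_flags,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
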