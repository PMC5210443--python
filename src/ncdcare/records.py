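"""Domain types and file I/O shared by the screening, engine, simulation and
evaluation modules.

The central container is the :class:`CohortPanel`: a long-format person x time
table with at most one row per (patient, visit month) and *monotone*
missingness — once a patient misses a follow-up, no later rows exist.  Under
staggered enrollment with a fixed program end this arises by construction
(administrative censoring); the validator flags any intermittent gap because
real intermittent missingness would change what the marginal models estimate.

Visits sit on a 3-monthly grid: one baseline visit (month 0) and six
follow-ups at 3, 6, 9, 12, 15 and 18 months.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel

VISIT_GRID: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18)

SEXES = ("female", "male")
DISEASE_GROUPS = ("htn_only", "dm_only", "both")
STATUS_LEVELS = ("none", "known", "new")

#: The input contract of the decision-support engine: 23 distinct data points
#: collected by the nurse care coordinator at each encounter.  Core
#: measurements are explicit fields of :class:`VisitMeasurements`; the rest
#: travel in ``history_fields``.
CORE_DATA_POINTS: tuple[str, ...] = (
    "age",
    "sex",
    "visit_month",
    "sbp",
    "dbp",
    "fpg",
    "fasting_flag",
    "current_medications",
)
HISTORY_DATA_POINTS: tuple[str, ...] = (
    "tobacco_use",
    "alcohol_use",
    "known_hypertension",
    "known_diabetes",
    "prior_cvd",
    "prior_stroke",
    "prior_ckd",
    "pregnancy",
    "chest_pain",
    "breathlessness",
    "hypoglycemia_symptoms",
    "family_history_cvd",
    "weight_kg",
    "height_cm",
    "waist_cm",
)
MDSS_DATA_POINTS: tuple[str, ...] = CORE_DATA_POINTS + HISTORY_DATA_POINTS


class SchemaError(ValueError):
    """A file or record does not match the published panel layout."""


class ValidationError(ValueError):
    """A record violates a stated invariant."""


@dataclass(frozen=True)
class PatientRecord:
    """One person's demographics and diagnosis status.

    ``htn_status`` / ``dm_status`` distinguish *known* disease (diagnosed
    before contact with the program) from *new* disease (detected by
    opportunistic screening); ``new`` is only assignable after a screening
    event.  ``enrollment_month`` is calendar time since program start
    (0-based, within the 21-month enrollment window); within-patient visit
    timing is kept separately as months since enrollment.
    """

    patient_id: str
    age: int
    sex: str
    site: str
    enrollment_month: int = 0
    htn_status: str = "none"
    dm_status: str = "none"

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0 <= self.enrollment_month <= 20:
            raise ValidationError(
                f"enrollment_month must be in [0, 20], got {self.enrollment_month}"
            )
        for name in ("htn_status", "dm_status"):
            if getattr(self, name) not in STATUS_LEVELS:
                raise ValidationError(
                    f"{name} must be one of {STATUS_LEVELS}, got {getattr(self, name)!r}"
                )

    @property
    def enrolled(self) -> bool:
        return self.htn_status != "none" or self.dm_status != "none"

    @property
    def disease_group(self) -> str | None:
        has_htn = self.htn_status != "none"
        has_dm = self.dm_status != "none"
        if has_htn and has_dm:
            return "both"
        if has_htn:
            return "htn_only"
        if has_dm:
            return "dm_only"
        return None


@dataclass(frozen=True)
class VisitMeasurements:
    """The engine's input for one encounter.

    ``visit_month`` is months since enrollment on the 3-monthly grid.  Blood
    pressure is in mm Hg, fasting plasma glucose in mg/dL.  ``fpg`` may only
    be present when the patient attended fasting — non-fasting glucose goes
    through the confirmatory-revisit pathway instead and is not stored here.
    """

    visit_month: int
    sbp: float | None = None
    dbp: float | None = None
    fpg: float | None = None
    fasting_flag: bool = False
    current_medications: tuple[tuple[str, float], ...] = ()
    history_fields: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.visit_month not in VISIT_GRID:
            raise ValidationError(
                f"visit_month must be one of {VISIT_GRID}, got {self.visit_month}"
            )
        if (self.sbp is None) != (self.dbp is None):
            raise ValidationError("sbp and dbp must be present together")
        if self.sbp is not None and not (self.sbp > self.dbp > 0):
            raise ValidationError(
                f"require sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}"
            )
        if self.fpg is not None:
            if self.fpg <= 0:
                raise ValidationError(f"fpg must be positive, got {self.fpg}")
            if not self.fasting_flag:
                raise ValidationError("fpg present but fasting_flag is false")
        unknown = set(self.history_fields) - set(HISTORY_DATA_POINTS)
        if unknown:
            raise ValidationError(
                f"history fields not in the {len(MDSS_DATA_POINTS)}-point schema: "
                f"{sorted(unknown)}"
            )


# ---------------------------------------------------------------------------
# CohortPanel


class PanelRow(BaseModel):
    """Published record layout for one panel row (one visit)."""

    patient_id: str
    site: str
    age: int
    sex: str
    new_flag: bool
    disease_group: str
    visit_month: int
    sbp: float | None = None
    dbp: float | None = None
    fpg: float | None = None
    fasting_flag: bool = False


PANEL_COLUMNS: tuple[str, ...] = tuple(PanelRow.model_fields)


def panel_json_schema() -> dict:
    """JSON schema of the panel record layout (one object per visit row)."""
    return PanelRow.model_json_schema()


def _row_problems(row: Mapping[str, Any]) -> list[str]:
    """Invariant check for a single panel row; returns human-readable defects."""
    problems: list[str] = []
    try:
        age = int(row["age"])
        if age < 0:
            problems.append("age < 0")
    except (TypeError, ValueError):
        problems.append("age not an integer")
    if row["sex"] not in SEXES:
        problems.append(f"sex not in {SEXES}")
    if row["disease_group"] not in DISEASE_GROUPS:
        problems.append(f"disease_group not in {DISEASE_GROUPS}")
    try:
        m = int(row["visit_month"])
        if m not in VISIT_GRID:
            problems.append(f"visit_month not on grid {VISIT_GRID}")
    except (TypeError, ValueError):
        problems.append("visit_month not an integer")
    sbp, dbp = row.get("sbp"), row.get("dbp")
    sbp_ok = sbp is not None and not pd.isna(sbp)
    dbp_ok = dbp is not None and not pd.isna(dbp)
    if sbp_ok != dbp_ok:
        problems.append("sbp/dbp must be present together")
    elif sbp_ok and not (float(sbp) > float(dbp) > 0):
        problems.append("require sbp > dbp > 0")
    fpg = row.get("fpg")
    if fpg is not None and not pd.isna(fpg):
        if float(fpg) <= 0:
            problems.append("fpg <= 0")
        if not bool(row.get("fasting_flag", False)):
            problems.append("fpg present but fasting_flag false")
    return problems


def validate_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Row-level invariant scan.

    Returns a diagnostics frame with one row per defective input row
    (columns: ``row``, ``patient_id``, ``problem``); empty when the panel
    is clean.
    """
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        for problem in _row_problems(row):
            records.append({"row": idx, "patient_id": row["patient_id"], "problem": problem})
    return pd.DataFrame(records, columns=["row", "patient_id", "problem"])


def intermittent_gap_patients(df: pd.DataFrame) -> list[str]:
    """Patients whose observed visit months are not a contiguous prefix of the grid.

    Monotone missingness means each patient's visits are {0, 3, ..., 3k};
    a patient seen at months 0 and 6 but not 3 has an intermittent gap.
    """
    flagged = []
    for pid, sub in df.groupby("patient_id", sort=False):
        months = sorted(int(m) for m in sub["visit_month"].unique())
        expected = list(VISIT_GRID[: len(months)])
        if months != expected:
            flagged.append(str(pid))
    return flagged


@dataclass
class CohortPanel:
    """Long-format person x time outcome table.

    Wraps a validated :class:`pandas.DataFrame` with columns
    ``patient_id, site, age, sex, new_flag, disease_group, visit_month,
    sbp, dbp, fpg, fasting_flag`` and at most one row per
    (patient_id, visit_month).
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PANEL_COLUMNS) - set(self.df.columns)
        if missing:
            raise SchemaError(f"missing required columns: {sorted(missing)}")
        self.df = self.df.loc[:, list(PANEL_COLUMNS)].reset_index(drop=True)
        dup = self.df.duplicated(subset=["patient_id", "visit_month"])
        if dup.any():
            raise ValidationError(
                "duplicate (patient_id, visit_month) rows: "
                f"{self.df.loc[dup, ['patient_id', 'visit_month']].to_dict('records')[:5]}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortPanel):
            return NotImplemented
        a = self.df.sort_values(["patient_id", "visit_month"]).reset_index(drop=True)
        b = other.df.sort_values(["patient_id", "visit_month"]).reset_index(drop=True)
        return a.equals(b)

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    def patients(self) -> pd.DataFrame:
        """One row per patient (baseline attributes)."""
        return (
            self.df.sort_values("visit_month")
            .groupby("patient_id", sort=False)
            .first()
            .reset_index()[
                ["patient_id", "site", "age", "sex", "new_flag", "disease_group"]
            ]
        )

    def check_monotone(self, warn: bool = True) -> list[str]:
        flagged = intermittent_gap_patients(self.df)
        if flagged and warn:
            warnings.warn(
                f"intermittent missingness for {len(flagged)} patient(s): "
                f"{flagged[:10]}",
                stacklevel=2,
            )
        return flagged


_READ_DTYPES = {
    "patient_id": str,
    "site": str,
    "age": "int64",
    "sex": str,
    "disease_group": str,
    "visit_month": "int64",
    "sbp": "float64",
    "dbp": "float64",
    "fpg": "float64",
}


def read_visits(path: str | Path, on_invalid: str = "drop") -> CohortPanel:
    """Read a visit CSV into a validated :class:`CohortPanel`.

    Rows violating a type invariant are rejected with row-level diagnostics
    (``on_invalid='drop'`` warns and removes them; ``'raise'`` aborts).
    Intermittent missingness triggers a warning naming the patients but does
    not reject rows — it is a cohort-level signal, not a row defect.
    """
    if on_invalid not in ("drop", "raise"):
        raise ValueError("on_invalid must be 'drop' or 'raise'")
    df = pd.read_csv(path, dtype=_READ_DTYPES, float_precision="round_trip")
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns: {sorted(missing)}")
    for col in ("new_flag", "fasting_flag"):
        df[col] = df[col].map(
            {True: True, False: False, "True": True, "False": False}
        )
        if df[col].isna().any():
            raise SchemaError(f"{path}: column {col} must be True/False")
        df[col] = df[col].astype(bool)
    diagnostics = validate_rows(df)
    if len(diagnostics):
        msg = (
            f"{path}: {len(diagnostics)} invalid row(s); first problems: "
            f"{diagnostics.head(5).to_dict('records')}"
        )
        if on_invalid == "raise":
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
        df = df.drop(index=diagnostics["row"].unique()).reset_index(drop=True)
    panel = CohortPanel(df)
    panel.check_monotone(warn=True)
    return panel


def write_visits(panel: CohortPanel, path: str | Path) -> Path:
    """Write a panel as comma-separated UTF-8 with header; empty field = missing.

    Round-trips bit-exactly through :func:`read_visits` (floats use Python's
    shortest-repr formatting).
    """
    path = Path(path)
    # %.17g preserves every float64 bit-exactly across the round trip
    panel.df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    return path


def write_panel_schema(path: str | Path) -> Path:
    """Publish the panel record layout as a JSON schema document."""
    path = Path(path)
    path.write_text(json.dumps(panel_json_schema(), indent=2), encoding="utf-8")
    return path
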