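import numpy as np
import pandas as pd
import pytest

from ncdcare import CohortPanel, load_ruleset

# Per-site screening-yield cell counts as printed in the program's yield
# table: (hypertension, diabetes, both) x (first column, second column).
# The program's own text and table disagree on which column is "known" and
# which "newly detected", so tests pick the labeling explicitly.
YIELD_CELLS = {
    "Kunihar": (534, 598, 85, 200, 54, 154),
    "Syri": (173, 330, 12, 28, 8, 37),
    "Dharampur": (665, 255, 51, 19, 55, 47),
    "Dharlagarh": (414, 353, 24, 22, 14, 24),
    "Nalagarh": (1161, 798, 82, 258, 74, 268),
}


@pytest.fixture(scope="session")
def ruleset():
    return load_ruleset()


def build_yield_panel(first_column_is_known: bool) -> CohortPanel:
    """Baseline-only panel reproducing the printed screening-yield cells.

    ``first_column_is_known`` selects the labeling: True follows the printed
    column headers, False follows the text's newly-detected counts.
    """
    rows = []
    pid = 0
    for site, cells in YIELD_CELLS.items():
        for (group, flag_first), count in zip(
            [
                ("htn_only", True), ("htn_only", False),
                ("dm_only", True), ("dm_only", False),
                ("both", True), ("both", False),
            ],
            cells,
        ):
            known = flag_first if first_column_is_known else not flag_first
            for _ in range(count):
                rows.append(
                    {
                        "patient_id": f"Y{pid:05d}",
                        "site": site,
                        "age": 55,
                        "sex": "female",
                        "new_flag": not known,
                        "disease_group": group,
                        "visit_month": 0,
                        "sbp": 152.0 if group != "dm_only" else np.nan,
                        "dbp": 94.0 if group != "dm_only" else np.nan,
                        "fpg": 160.0 if group != "htn_only" else np.nan,
                        "fasting_flag": group != "htn_only",
                    }
                )
                pid += 1
    return CohortPanel(pd.DataFrame(rows))


def make_complete_panel(
    n: int,
    effects: dict[int, float],
    sd: float = 10.0,
    rho: float = 0.5,
    seed: int = 0,
    baseline: float = 146.0,
    outcome: str = "sbp",
) -> CohortPanel:
    """Balanced panel: every patient observed at every month in the grid."""
    rng = np.random.default_rng(seed)
    months = sorted({0} | set(effects))
    sites = ["Kunihar", "Syri", "Dharampur", "Dharlagarh", "Nalagarh"]
    rows = []
    u = rng.normal(0, sd * np.sqrt(rho), size=n)
    for i in range(n):
        site = sites[i % 5]
        sex = "male" if i % 2 else "female"
        new = bool(i % 3 == 0)
        for m in months:
            y = (
                baseline
                + effects.get(m, 0.0)
                + u[i]
                + rng.normal(0, sd * np.sqrt(1 - rho))
            )
            row = {
                "patient_id": f"C{i:05d}",
                "site": site,
                "age": 40 + (i % 30),
                "sex": sex,
                "new_flag": new,
                "disease_group": "htn_only" if outcome != "fpg" else "dm_only",
                "visit_month": m,
                "sbp": np.nan,
                "dbp": np.nan,
                "fpg": np.nan,
                "fasting_flag": False,
            }
            if outcome == "fpg":
                row["fpg"] = y
                row["fasting_flag"] = True
            else:
                row["sbp"] = y
                row["dbp"] = y - 55.0
            rows.append(row)
    return CohortPanel(pd.DataFrame(rows))


def mean_difference_oracle(panel: CohortPanel, outcome: str) -> dict[int, float]:
    """Brute-force per-timepoint (mean_t - mean_0) on the raw data."""
    df = panel.df[panel.df[outcome].notna()]
    means = df.groupby("visit_month")[outcome].mean()
    return {int(m): float(means[m] - means[0]) for m in means.index if m != 0}
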