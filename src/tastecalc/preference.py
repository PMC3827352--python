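"""Two-bottle preference test analysis.

Each test concentration is offered against water for 48 h, with the bottle
sides swapped after 24 h so that side preferences cancel.  The preference
ratio pools volumes over the two 24 h periods:

    ratio = Σ test intake / Σ (test intake + water intake)

Group dose-response series are compared with a mixed repeated-measures
two-way ANOVA (between factor: diet group; within factor: concentration)
with Bonferroni-adjusted per-concentration contrasts, plus unadjusted
Student t-tests per concentration as a second tier.  Significance at
p < 0.05.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg

from .stats import ALPHA, StatsError, significance_stars, two_sample_t

logger = logging.getLogger(__name__)

#: Expected columns of an intake table.
INTAKE_COLUMNS = (
    "animal_id", "group", "stimulus", "concentration_mM", "period",
    "test_intake_ml", "water_intake_ml",
)


class PreferenceError(ValueError):
    pass


def preference_ratio(records: pd.DataFrame, n_periods: int = 2) -> float:
    """48 h preference ratio for one animal × concentration.

    ``records`` holds that animal/concentration's per-period rows; both
    periods must be present and total intake must be positive.
    """
    periods = set(records["period"])
    missing = set(range(1, n_periods + 1)) - periods
    if missing:
        raise PreferenceError(f"missing period(s) {sorted(missing)}")
    test = float(records["test_intake_ml"].sum())
    total = test + float(records["water_intake_ml"].sum())
    if total <= 0:
        raise PreferenceError("zero total intake; preference ratio undefined")
    return test / total


def preference_table(intake: pd.DataFrame, n_periods: int = 2) -> pd.DataFrame:
    """Per animal × stimulus × concentration 48 h ratios (long format).

    Output columns: animal_id, group, stimulus, concentration_mM, preference.
    """
    missing_cols = set(INTAKE_COLUMNS) - set(intake.columns)
    if missing_cols:
        raise PreferenceError(f"intake table missing columns {sorted(missing_cols)}")
    if intake.empty:
        raise PreferenceError("intake table is empty")
    rows = []
    keys = ["animal_id", "group", "stimulus", "concentration_mM"]
    for key, sub in intake.groupby(keys, sort=True):
        rows.append(dict(zip(keys, key)) | {
            "preference": preference_ratio(sub, n_periods)
        })
    return pd.DataFrame(rows)


def _check_complete(ratios: pd.DataFrame) -> None:
    pivot = ratios.pivot_table(
        index="animal_id", columns="concentration_mM", values="preference",
        aggfunc="count", fill_value=0,
    )
    missing = [
        (animal, conc)
        for animal in pivot.index
        for conc in pivot.columns
        if pivot.loc[animal, conc] == 0
    ]
    if missing:
        raise PreferenceError(f"incomplete concentration series: missing {missing}")


def rm_two_way_anova(
    ratios: pd.DataFrame,
    correction: bool = False,
) -> dict[str, pd.DataFrame]:
    """Mixed repeated-measures ANOVA on preference ratios.

    Between-subject factor: diet group; within-subject factor: concentration
    (each animal drinks the full ascending series).  Returns the ANOVA table
    plus Bonferroni-adjusted per-concentration group contrasts.
    ``correction`` enables the Greenhouse–Geisser sphericity correction
    (off by default).
    """
    groups = sorted(ratios["group"].unique())
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    for g in groups:
        if ratios.loc[ratios["group"] == g, "animal_id"].nunique() < 2:
            raise StatsError(f"group {g!r} has fewer than 2 animals")
    _check_complete(ratios)
    aov = pg.mixed_anova(
        data=ratios, dv="preference", within="concentration_mM",
        subject="animal_id", between="group", correction=correction,
    )
    contrasts = per_concentration_tests(ratios)
    n_conc = contrasts.shape[0]
    contrasts = contrasts.assign(
        p_adj=np.minimum(1.0, contrasts["p"] * n_conc)
    )
    contrasts["stars"] = contrasts["p_adj"].map(significance_stars)
    return {"anova": aov, "contrasts": contrasts}


def per_concentration_tests(
    ratios: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Unadjusted two-sample Student t-test on ratios at each concentration
    (two groups)."""
    groups = sorted(ratios["group"].unique())
    if len(groups) != 2:
        raise StatsError(f"per-concentration t-tests need exactly 2 groups, got {groups}")
    rows = []
    for conc, sub in ratios.groupby("concentration_mM", sort=True):
        a = sub.loc[sub["group"] == groups[0], "preference"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "preference"].to_numpy()
        t, p = two_sample_t(a, b, equal_var=equal_var)
        rows.append({
            "concentration_mM": conc, "group1": groups[0], "group2": groups[1],
            "n1": a.size, "n2": b.size, "t": t, "p": p,
            "significant": p < ALPHA,
        })
    return pd.DataFrame(rows)


def dose_curve_summary(ratios: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD preference per group × concentration (plotting convention:
    group means with standard deviation)."""
    return (
        ratios.groupby(["group", "concentration_mM"], sort=True)["preference"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
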