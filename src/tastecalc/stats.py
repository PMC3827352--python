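"""Cohort-level statistics for responder frequencies and response properties.

Responder frequencies are compared with Pearson chi-square tests on
cohort × (responsive, non-responsive) contingency tables, without Yates
continuity correction by default (a correction flag is available for
sensitivity analysis).  Response properties (amplitude %, AUC, duration)
are compared with one-way ANOVA followed by pairwise Student t-tests with
Bonferroni adjustment; only evoked responses enter these comparisons (null
responses carry no amplitude).  Significance is declared at p < 0.05 with
the conventional star notation (*** p<0.001, ** p<0.01, * p<0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .celltypes import CellProfile

logger = logging.getLogger(__name__)

ALPHA = 0.05


class StatsError(ValueError):
    pass


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# responder frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """Responsive / non-responsive counts per cohort for one stimulus."""

    stimulus: str
    cohorts: tuple[str, ...]
    counts: np.ndarray  # shape (n_cohorts, 2): [responsive, non_responsive]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.cohorts), 2):
            raise StatsError("counts must be (n_cohorts, 2)")
        if np.any(counts < 0):
            raise StatsError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts[:, 0] / self.counts.sum(axis=1)


def build_responder_table(
    profiles: Iterable[CellProfile],
    stimulus: str,
    cohorts: Sequence[str],
    responsive_ids: set[str] | None = None,
) -> ContingencyTable:
    """Count responsive vs non-responsive cells per cohort for one stimulus.

    For MPG the caller passes ``responsive_ids`` from
    :func:`tastecalc.celltypes.select_umami_responses` (and pre-filters the
    profiles to KCl-negative cells); every profile must carry a call for the
    stimulus.
    """
    rows = []
    for cohort in cohorts:
        members = [p for p in profiles if p.group == cohort]
        if not members:
            raise StatsError(f"cohort {cohort!r} has no cells")
        n_resp = 0
        for prof in members:
            call = prof.calls.get(stimulus)
            if call is None:
                raise StatsError(
                    f"cell {prof.cell_id} was not tested for {stimulus}"
                )
            if responsive_ids is not None:
                n_resp += prof.cell_id in responsive_ids
            else:
                n_resp += bool(call.responsive)
        rows.append([n_resp, len(members) - n_resp])
    return ContingencyTable(stimulus, tuple(cohorts), np.array(rows))


def chi_square_independence(
    table: ContingencyTable | np.ndarray, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square of independence; Yates correction off by default.

    Returns ``(statistic, df, p)``.  Raises on a zero row or column marginal
    (expected counts would vanish).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise StatsError("contingency table has a zero marginal")
    res = sps.chi2_contingency(counts, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pairwise_frequency_tests(
    table: ContingencyTable, reference: str, correction: bool = False
) -> pd.DataFrame:
    """Per-cohort 2×2 chi-squares against a reference cohort (unadjusted,
    matching per-bar comparisons); the omnibus 2×k test is available via
    :func:`chi_square_independence` on the full table."""
    ref_idx = table.cohorts.index(reference)
    rows = []
    for i, cohort in enumerate(table.cohorts):
        if i == ref_idx:
            continue
        sub = table.counts[[ref_idx, i]]
        stat, df, p = chi_square_independence(sub, correction=correction)
        rows.append({
            "stimulus": table.stimulus, "cohort": cohort, "reference": reference,
            "statistic": stat, "df": df, "p": p, "stars": significance_stars(p),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response-property comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """One-way ANOVA over groups plus Bonferroni-adjusted pairwise t-tests."""

    measure: str
    stimulus: str
    groups: tuple[str, ...]
    n_per_group: dict[str, int]
    f_statistic: float
    p: float
    pairwise: pd.DataFrame = field(repr=False)  # group1, group2, t, p_raw, p_adj

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided Student t-test (pooled variance by default; Welch via flag).

    Degenerate input (zero variance in both groups with equal means) returns
    ``(0.0, 1.0)`` by convention, with a logged warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            logger.warning("degenerate t-test: zero variance, equal means; p=1")
            return 0.0, 1.0
        logger.warning("degenerate t-test: zero variance, unequal means; p=0")
        return float("inf") if np.mean(a) > np.mean(b) else float("-inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def one_way_anova_bonferroni(
    samples: dict[str, Sequence[float]],
    measure: str = "amplitude_pct",
    stimulus: str = "",
    equal_var: bool = True,
) -> GroupComparison:
    """Standard one-way F-test plus all pairwise t-tests with Bonferroni
    multiplication by the number of pairs."""
    if len(samples) < 2:
        raise StatsError("need at least 2 groups")
    arrays = {}
    for name, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise StatsError(f"group {name!r} has n={arr.size} (< 2)")
        arrays[name] = arr
    f_stat, p = sps.f_oneway(*arrays.values())
    pairs = list(combinations(arrays, 2))
    rows = []
    for g1, g2 in pairs:
        t, p_raw = two_sample_t(arrays[g1], arrays[g2], equal_var=equal_var)
        p_adj = min(1.0, p_raw * len(pairs))
        rows.append({
            "group1": g1, "group2": g2, "t": t, "p_raw": p_raw, "p_adj": p_adj,
            "stars": significance_stars(p_adj),
        })
    return GroupComparison(
        measure=measure, stimulus=stimulus, groups=tuple(arrays),
        n_per_group={g: int(v.size) for g, v in arrays.items()},
        f_statistic=float(f_stat), p=float(p),
        pairwise=pd.DataFrame(rows),
    )


def comparison_table(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Tidy results table: one row per pairwise contrast with the omnibus F."""
    rows = []
    for comp in comparisons:
        for rec in comp.pairwise.to_dict("records"):
            rows.append({
                "stimulus": comp.stimulus, "measure": comp.measure,
                "group1": rec["group1"], "group2": rec["group2"],
                "n1": comp.n_per_group[rec["group1"]],
                "n2": comp.n_per_group[rec["group2"]],
                "F": comp.f_statistic, "anova_p": comp.p,
                "t": rec["t"], "p_raw": rec["p_raw"], "p_adj": rec["p_adj"],
                "stars": rec["stars"],
            })
    return pd.DataFrame(rows)
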