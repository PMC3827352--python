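"""Compare responder frequencies and response properties across cohorts.

Builds per-stimulus contingency tables (with MPG restricted to KCl-negative
cells), runs pairwise chi-squares of each obese cohort against control, and
one-way ANOVAs with Bonferroni post-hoc on amplitude, AUC and duration of
evoked responses.

Run after 02:  python analysis/03_cohort_statistics.py
"""

from pathlib import Path

import pandas as pd

from tastecalc.celltypes import select_umami_responses
from tastecalc.io import frame_to_calls
from tastecalc.celltypes import profiles_from_calls
from tastecalc.stats import (
    build_responder_table,
    comparison_table,
    one_way_anova_bonferroni,
    pairwise_frequency_tests,
)

OUTDIR = Path("results")
GROUPS = ("ctl", "obM", "obF")


def main() -> None:
    calls_df = pd.read_csv(OUTDIR / "response_calls.csv")
    profiles = []
    for group in GROUPS:
        sub = calls_df[calls_df["group"] == group].drop(columns=["group"])
        profiles.extend(profiles_from_calls(frame_to_calls(sub), group))

    umami_ids = {c.cell_id for c in select_umami_responses(profiles)
                 if c.responsive}

    freq_frames, comparisons = [], []
    for stim in ("SAC", "ACEK", "MPG", "DEN"):
        if stim == "MPG":
            pool = [p for p in profiles if p.kcl_responsive is False]
            table = build_responder_table(pool, stim, GROUPS,
                                          responsive_ids=umami_ids)
        else:
            table = build_responder_table(profiles, stim, GROUPS)
        freq = pairwise_frequency_tests(table, "ctl")
        freq_frames.append(freq)
        props = dict(zip(table.cohorts, (table.proportions * 100).round(1)))
        print(f"{stim}: responder % {props}")
        for _, row in freq.iterrows():
            print(f"    {row.cohort} vs ctl: chi2={row.statistic:.2f} "
                  f"p={row.p:.4f} {row.stars}")

        for measure in ("amplitude_pct", "auc", "duration_s"):
            samples = {}
            for group in GROUPS:
                sub = calls_df[
                    (calls_df["group"] == group)
                    & (calls_df["stimulus"] == stim)
                    & calls_df["responsive"]
                    & calls_df[measure].notna()
                ]
                if stim == "MPG":
                    sub = sub[sub["cell_id"].isin(umami_ids)]
                samples[group] = sub[measure].to_numpy()
            if all(len(v) >= 2 for v in samples.values()):
                comparisons.append(one_way_anova_bonferroni(
                    samples, measure=measure, stimulus=stim))

    pd.concat(freq_frames, ignore_index=True).to_csv(
        OUTDIR / "frequency_tests.csv", index=False)
    comp = comparison_table(comparisons)
    comp.to_csv(OUTDIR / "property_comparisons.csv", index=False)
    sig = comp[comp["p_adj"] < 0.05]
    print(f"\n{len(sig)} pairwise property contrasts significant after "
          f"Bonferroni adjustment; full table in "
          f"{OUTDIR / 'property_comparisons.csv'}")


if __name__ == "__main__":
    main()
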