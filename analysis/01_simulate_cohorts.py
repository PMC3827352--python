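"""Simulate the imaging cohorts.

Generates the three diet × sex cohorts (control, obese male, obese female)
of fura-2-like traces — four tastant epochs plus a 50 mM KCl epoch per cell
— at the calibrated amplitude presets, and writes the trace/epoch/ground
truth CSVs that the downstream steps consume.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

from pathlib import Path

from tastecalc.io import write_traces
from tastecalc.presets import cohort_config
from tastecalc.simulate import simulate_cohort

SEED = 20240901
N_CELLS = 120
OUTDIR = Path("results/cohorts")


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    for gi, group in enumerate(("ctl", "obM", "obF")):
        cfg = cohort_config(group, N_CELLS)
        traces, truth = simulate_cohort(cfg, seed=SEED + gi)
        write_traces(traces, OUTDIR / f"traces_{group}.csv",
                     OUTDIR / f"epochs_{group}.csv")
        truth.to_csv(OUTDIR / f"truth_{group}.csv", index=False)
        frac = truth.groupby("stimulus")["is_responder"].mean().round(3)
        print(f"{group}: {len(traces)} cells; true responder fractions:")
        print(frac.to_string(), "\n")
    print(f"wrote cohort CSVs to {OUTDIR}")


if __name__ == "__main__":
    main()
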