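"""End-to-end orchestration: simulate → quantify → type → compare, and
simulate-intake → preference statistics.

A run is described by a :class:`RunConfig` (YAML-serialisable); every run
writes a manifest recording the seed, a hash of the resolved configuration
and the package version, so any numeric output is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .celltypes import profiles_from_calls, select_umami_responses, type_counts
from .io import calls_to_frame, dump_yaml, write_traces
from .presets import PREFERENCE_SERIES_MM, cohort_config
from .preference import (
    dose_curve_summary,
    per_concentration_tests,
    preference_table,
    rm_two_way_anova,
)
from .quantify import QuantConfig, quantify_cell
from .simulate import IntakeGenParams, simulate_cohort, simulate_preference_records
from .stats import (
    build_responder_table,
    chi_square_independence,
    comparison_table,
    one_way_anova_bonferroni,
    pairwise_frequency_tests,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Reproducible run description (all fields YAML-serialisable)."""

    seed: int = 0
    outdir: str = "results"
    groups: tuple[str, ...] = ("ctl", "obM", "obF")
    n_cells: int = 50
    stimuli: tuple[str, ...] = ("SAC", "ACEK", "MPG", "DEN")
    # detection parameters
    baseline_window_s: float = 30.0
    min_run: int = 3
    post_window_s: float = 60.0
    return_band_k: float = 2.0
    return_run: int = 3
    # statistics flags
    yates_correction: bool = False
    welch: bool = False
    gg_correction: bool = False
    # preference arm
    n_animals: int = 5
    preference_stimuli: tuple[str, ...] = ("ACEK", "SAC", "MPG", "DEN")
    true_preference: dict = field(default_factory=dict)  # group -> stimulus -> value
    write_trace_csv: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ConfigError("seed must be a non-negative integer")

    def quant_config(self) -> QuantConfig:
        return QuantConfig(
            baseline_window_s=self.baseline_window_s, min_run=self.min_run,
            post_window_s=self.post_window_s, return_band_k=self.return_band_k,
            return_run=self.return_run,
        )

    @classmethod
    def from_yaml_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("groups", "stimuli", "preference_stimuli"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: RunConfig, outdir: Path, outputs: list[str]) -> Path:
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "tastecalc_version": __version__,
        "outputs": sorted(outputs),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_imaging_pipeline(config: RunConfig) -> dict[str, Path]:
    """Simulate cohorts, quantify every cell, gate umami responses by KCl,
    and write responder-frequency and response-property comparisons."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc = config.quant_config()

    all_calls, truth_frames, profiles = [], [], []
    for gi, group in enumerate(config.groups):
        cc = cohort_config(group, config.n_cells, config.stimuli)
        traces, truth = simulate_cohort(cc, seed=config.seed * 1000 + gi)
        truth_frames.append(truth)
        if config.write_trace_csv:
            write_traces(traces, outdir / f"traces_{group}.csv",
                         outdir / f"epochs_{group}.csv")
        for tr in traces:
            all_calls.extend(quantify_cell(tr, qc))
        profiles.extend(profiles_from_calls(
            [c for c in all_calls if c.cell_id.startswith(f"{group}_")], group
        ))

    calls_df = calls_to_frame(all_calls)
    typing_rows = [{
        "cell_id": p.cell_id, "group": p.group,
        "kcl_responsive": p.kcl_responsive, "inferred_type": p.inferred_type,
    } for p in profiles]
    typing_df = pd.DataFrame(typing_rows)

    umami_calls = select_umami_responses(profiles)
    umami_ids = {c.cell_id for c in umami_calls if c.responsive}

    freq_rows, contingency_rows = [], []
    comparisons = []
    reference = config.groups[0]
    for stim in config.stimuli:
        if stim == "MPG":
            pool = [p for p in profiles if p.kcl_responsive is False]
            table = build_responder_table(pool, stim, config.groups,
                                          responsive_ids=umami_ids)
        else:
            pool = profiles
            table = build_responder_table(pool, stim, config.groups)
        for cohort, (n_resp, n_non) in zip(table.cohorts, table.counts):
            contingency_rows.append({
                "stimulus": stim, "cohort": cohort,
                "responsive": int(n_resp), "non_responsive": int(n_non),
            })
        freq_rows.append(pairwise_frequency_tests(
            table, reference, correction=config.yates_correction))
        omnibus_stat, omnibus_df, omnibus_p = chi_square_independence(
            table, correction=config.yates_correction)
        logger.info("%s omnibus chi2=%.3f df=%d p=%.4g",
                    stim, omnibus_stat, omnibus_df, omnibus_p)

        for measure in ("amplitude_pct", "auc", "duration_s"):
            samples = {}
            for group in config.groups:
                sub = calls_df[
                    (calls_df["stimulus"] == stim)
                    & calls_df["responsive"]
                    & calls_df["cell_id"].str.startswith(f"{group}_")
                    & calls_df[measure].notna()
                ]
                if stim == "MPG":
                    sub = sub[sub["cell_id"].isin(umami_ids)]
                samples[group] = sub[measure].to_numpy()
            if all(len(v) >= 2 for v in samples.values()):
                comparisons.append(one_way_anova_bonferroni(
                    samples, measure=measure, stimulus=stim,
                    equal_var=not config.welch))
            else:
                logger.warning("skipping %s/%s ANOVA: a group has n < 2",
                               stim, measure)

    outputs = {
        "calls": outdir / "response_calls.csv",
        "typing": outdir / "cell_types.csv",
        "truth": outdir / "ground_truth.csv",
        "contingency": outdir / "responder_counts.csv",
        "frequency_tests": outdir / "frequency_tests.csv",
        "comparisons": outdir / "property_comparisons.csv",
    }
    calls_df.to_csv(outputs["calls"], index=False)
    typing_df.to_csv(outputs["typing"], index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(outputs["truth"], index=False)
    pd.DataFrame(contingency_rows).to_csv(outputs["contingency"], index=False)
    pd.concat(freq_rows, ignore_index=True).to_csv(
        outputs["frequency_tests"], index=False)
    comparison_table(comparisons).to_csv(outputs["comparisons"], index=False)
    logger.info("cell-type counts: %s", type_counts(profiles))
    outputs["manifest"] = _write_manifest(
        config, outdir, [p.name for p in outputs.values()])
    return outputs


_DEFAULT_TRUE_PREFERENCE = {
    # free generator parameters: appetitive stimuli preferred at higher
    # concentrations by controls, blunted in the obese group; denatonium
    # avoided by controls and less so by obese animals.
    "ctl": {"ACEK": {1.0: 0.5, 2.0: 0.6, 20.0: 0.8, 50.0: 0.85},
            "SAC": {1.0: 0.6, 2.0: 0.7, 10.0: 0.85, 20.0: 0.85},
            "MPG": {10.0: 0.5, 30.0: 0.5, 100.0: 0.55, 300.0: 0.65},
            "DEN": {0.1: 0.5, 0.5: 0.4, 1.0: 0.3, 10.0: 0.1}},
    "ob": {"ACEK": {1.0: 0.5, 2.0: 0.55, 20.0: 0.6, 50.0: 0.6},
           "SAC": {1.0: 0.5, 2.0: 0.55, 10.0: 0.8, 20.0: 0.85},
           "MPG": {10.0: 0.5, 30.0: 0.5, 100.0: 0.5, 300.0: 0.5},
           "DEN": {0.1: 0.5, 0.5: 0.45, 1.0: 0.35, 10.0: 0.25}},
}


def run_preference_pipeline(config: RunConfig) -> dict[str, Path]:
    """Simulate two-bottle intake for each stimulus and both diet groups,
    compute 48 h ratios, and run the concentration-series statistics."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefs = config.true_preference or _DEFAULT_TRUE_PREFERENCE

    intake_frames, ratio_frames, anova_rows, ttest_frames, dose_frames = \
        [], [], [], [], []
    for si, stim in enumerate(config.preference_stimuli):
        series = PREFERENCE_SERIES_MM[stim.upper()]
        per_stim = []
        for gi, group in enumerate(sorted(prefs)):
            params = IntakeGenParams(
                group=group, stimulus=stim, concentrations_mm=series,
                true_preference={
                    float(k): float(v) for k, v in prefs[group][stim].items()
                },
                n_animals=config.n_animals,
            )
            records = simulate_preference_records(
                params, seed=config.seed * 1000 + 100 * si + gi)
            intake_frames.append(records)
            per_stim.append(preference_table(records))
        ratios = pd.concat(per_stim, ignore_index=True)
        ratio_frames.append(ratios)
        result = rm_two_way_anova(ratios, correction=config.gg_correction)
        aov = result["anova"].assign(stimulus=stim)
        anova_rows.append(aov)
        ttest_frames.append(
            per_concentration_tests(ratios, equal_var=not config.welch)
            .assign(stimulus=stim))
        dose_frames.append(dose_curve_summary(ratios).assign(stimulus=stim))

    outputs = {
        "intake": outdir / "intake_records.csv",
        "ratios": outdir / "preference_ratios.csv",
        "anova": outdir / "preference_anova.csv",
        "ttests": outdir / "preference_ttests.csv",
        "dose_curves": outdir / "dose_curves.csv",
    }
    pd.concat(intake_frames, ignore_index=True).to_csv(outputs["intake"], index=False)
    pd.concat(ratio_frames, ignore_index=True).to_csv(outputs["ratios"], index=False)
    pd.concat(anova_rows, ignore_index=True).to_csv(outputs["anova"], index=False)
    pd.concat(ttest_frames, ignore_index=True).to_csv(outputs["ttests"], index=False)
    pd.concat(dose_frames, ignore_index=True).to_csv(outputs["dose_curves"], index=False)
    outputs["manifest"] = _write_manifest(
        config, outdir, [p.name for p in outputs.values()])
    return outputs


def save_config(config: RunConfig, path: Path) -> None:
    dump_yaml(asdict(config), path)
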