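"""Simulation-recovery runs: generate preset cohorts and measure how well
the quantification pipeline recovers the configured ground truth.

These are the package's end-to-end self-checks: amplitude, duration and AUC
presets are calibrated to published group means, cohorts are simulated at
those operating points, and the full baseline → detection → localisation →
quantification path is run on every trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .presets import DEFAULT_AMPLITUDE_CV, get_preset
from .quantify import DEFAULT_CONFIG, QuantConfig, quantify_epoch
from .simulate import simulate_preset_traces


@dataclass(frozen=True)
class RecoveryResult:
    """Cohort summary of one recovered measure."""

    preset: str
    measure: str
    mean: float
    sem: float
    n: int          # cells entering the summary
    n_simulated: int
    target: float | None = None


def _measure_cohort(
    preset_name: str, n: int, seed: int, config: QuantConfig = DEFAULT_CONFIG
) -> dict[str, np.ndarray]:
    preset = get_preset(preset_name)
    traces, _true_amps = simulate_preset_traces(
        preset.params, n, seed, amplitude_cv=preset.amplitude_cv
    )
    out: dict[str, list] = {"amplitude_pct": [], "duration_s": [], "auc": []}
    for tr in traces:
        call = quantify_epoch(tr, tr.epochs[0], config)
        if not call.responsive:
            continue
        out["amplitude_pct"].append(call.amplitude_pct)
        if not call.excluded_no_return:
            out["duration_s"].append(call.duration_s)
            out["auc"].append(call.auc)
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


def recover_measure(
    preset_name: str,
    measure: str,
    n: int = 500,
    seed: int = 1,
    config: QuantConfig = DEFAULT_CONFIG,
) -> RecoveryResult:
    """Simulate ``n`` responsive preset traces and report the pipeline's
    cohort mean of ``measure`` (amplitude_pct, duration_s or auc)."""
    values = _measure_cohort(preset_name, n, seed, config)[measure]
    preset = get_preset(preset_name)
    target = {
        "amplitude_pct": preset.params.amplitude_pct,
        "duration_s": preset.duration_target_s,
        "auc": preset.auc_target,
    }[measure]
    return RecoveryResult(
        preset=preset_name, measure=measure,
        mean=float(values.mean()), sem=float(values.std(ddof=1) / np.sqrt(values.size)),
        n=int(values.size), n_simulated=n, target=target,
    )


def recover_amplitude(preset_name: str, n: int = 500, seed: int = 1) -> RecoveryResult:
    return recover_measure(preset_name, "amplitude_pct", n, seed)


def recover_duration(preset_name: str, n: int = 500, seed: int = 1) -> RecoveryResult:
    return recover_measure(preset_name, "duration_s", n, seed)


def recover_auc(preset_name: str, n: int = 500, seed: int = 1) -> RecoveryResult:
    return recover_measure(preset_name, "auc", n, seed)
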