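"""Seeded generators for fura-2-like traces and two-bottle intake records.

Every downstream stage of the pipeline (detection, amplitude/AUC/duration
quantification, KCl gating, cohort statistics, preference analysis) is
exercised against data from this module, where the ground truth is known by
construction.

The evoked transient is an additive bump on a flat baseline: a saturating
exponential rise that reaches its peak ``3 * rise_tau`` after transient
onset (normalised so the peak value is attained exactly), followed by a pure
exponential decay with time constant ``decay_tau``.  The pure-exponential
tail is what makes duration calibration closed-form: the noise-free
transient re-enters the band ``baseline ± k * noise_sd`` at

    t_peak + decay_tau * ln(peak_delta / (k * noise_sd))

after onset, which :func:`calibrate_decay` inverts.

Randomness: one master seed; per-cell (and per-animal) substreams are
derived with :class:`numpy.random.SeedSequence` spawn keys, so cell ``i`` of
a cohort receives the same draws regardless of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trace import StimulusEpoch, Trace

#: Peak is reached this many rise time constants after transient onset.
RISE_TO_PEAK_FACTOR = 3.0


class ParamValidationError(ValueError):
    """A generator parameter violates its invariant; names the field."""


class InfeasibleCalibrationError(ValueError):
    """Requested duration/AUC cannot be met (peak not above the return band)."""


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceGenParams:
    """Parameters of one synthetic trace.

    ``amplitude_pct`` is the target true peak, in percent over baseline, so a
    responder's noise-free maximum is ``baseline_mean * (1 + amplitude_pct/100)``.
    """

    epoch: StimulusEpoch
    responder: bool = True
    amplitude_pct: float = 50.0
    baseline_mean: float = 1.0
    noise_sd: float = 0.002
    rise_tau: float = 2.0
    decay_tau: float = 12.0
    onset_latency: float = 2.0
    sampling_interval: float = 1.0
    duration_total: float = 240.0
    drift_per_s: float = 0.0  # optional slow linear baseline drift

    def validate(self) -> None:
        if self.noise_sd < 0:
            # zero is allowed: noise-free traces are the analytic ground truth
            raise ParamValidationError("noise_sd must be >= 0")
        if self.amplitude_pct < 0:
            raise ParamValidationError("amplitude_pct must be >= 0")
        if not self.rise_tau > 0:
            raise ParamValidationError("rise_tau must be > 0")
        if not self.decay_tau > 0:
            raise ParamValidationError("decay_tau must be > 0")
        if not self.sampling_interval > 0:
            raise ParamValidationError("sampling_interval must be > 0")
        if not self.baseline_mean > 0:
            raise ParamValidationError("baseline_mean must be > 0")
        if self.onset_latency < 0:
            raise ParamValidationError("onset_latency must be >= 0")
        if self.epoch.start_s < 0 or self.epoch.end_s > self.duration_total:
            raise ParamValidationError("epoch must fit within duration_total")


def transient_profile(
    times: np.ndarray,
    onset_s: float,
    peak_delta: float,
    rise_tau: float,
    decay_tau: float,
    sampling_interval: float,
) -> np.ndarray:
    """Noise-free additive transient evaluated on ``times``.

    The nominal time-to-peak ``RISE_TO_PEAK_FACTOR * rise_tau`` is snapped to
    the sample grid so the configured peak value appears exactly in the
    sampled trace.
    """
    t_peak_nominal = onset_s + RISE_TO_PEAK_FACTOR * rise_tau
    t_peak = onset_s + max(
        sampling_interval,
        round((t_peak_nominal - onset_s) / sampling_interval) * sampling_interval,
    )
    out = np.zeros_like(times, dtype=float)
    rising = (times > onset_s) & (times < t_peak)
    norm = 1.0 - math.exp(-(t_peak - onset_s) / rise_tau)
    out[rising] = peak_delta * (1.0 - np.exp(-(times[rising] - onset_s) / rise_tau)) / norm
    decaying = times >= t_peak
    out[decaying] = peak_delta * np.exp(-(times[decaying] - t_peak) / decay_tau)
    return out


def time_to_peak(rise_tau: float, sampling_interval: float = 1.0) -> float:
    """Grid-snapped onset-to-peak time used by :func:`transient_profile`."""
    nominal = RISE_TO_PEAK_FACTOR * rise_tau
    return max(sampling_interval, round(nominal / sampling_interval) * sampling_interval)


def simulate_trace(params: TraceGenParams, seed: int | np.random.SeedSequence) -> Trace:
    """One synthetic cell: baseline + Gaussian noise, plus a transient if responder."""
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_total / params.sampling_interval))
    times = np.arange(n, dtype=float) * params.sampling_interval
    ratio = params.baseline_mean + rng.normal(0.0, params.noise_sd, size=n)
    if params.drift_per_s:
        ratio += params.drift_per_s * times
    if params.responder and params.amplitude_pct > 0:
        onset = params.epoch.start_s + params.onset_latency
        peak_delta = params.amplitude_pct * params.baseline_mean / 100.0
        ratio += transient_profile(
            times, onset, peak_delta, params.rise_tau, params.decay_tau,
            params.sampling_interval,
        )
    return Trace(cell_id="sim", time=times, ratio=ratio, epochs=[params.epoch])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_decay(
    amplitude_pct: float,
    target_duration: float,
    baseline_mean: float = 1.0,
    noise_sd: float = 0.002,
    return_band_k: float = 2.0,
    rise_tau: float = 2.0,
    sampling_interval: float = 1.0,
) -> float:
    """Decay constant for which the noise-free transient re-enters the
    return band ``baseline ± return_band_k * noise_sd`` exactly
    ``target_duration`` seconds after onset.

    Closed form: ``decay_tau = (target_duration - t_peak) / ln(peak_delta / band)``.
    """
    peak_delta = amplitude_pct * baseline_mean / 100.0
    band = return_band_k * noise_sd
    if peak_delta <= band:
        raise InfeasibleCalibrationError(
            f"peak delta {peak_delta:.4g} does not exceed return band {band:.4g}"
        )
    t_peak = time_to_peak(rise_tau, sampling_interval)
    if target_duration <= t_peak:
        raise InfeasibleCalibrationError(
            f"target_duration {target_duration:.4g} s is within the rise portion "
            f"({t_peak:.4g} s to peak)"
        )
    return (target_duration - t_peak) / math.log(peak_delta / band)


def calibrate_auc(
    amplitude_pct: float,
    target_auc: float,
    baseline_mean: float = 1.0,
    noise_sd: float = 0.002,
    return_band_k: float = 2.0,
    rise_tau: float = 2.0,
    sampling_interval: float = 1.0,
) -> float:
    """Decay constant for which the noise-free transient's positive-part
    integral from onset to band re-entry equals ``target_auc`` (ratio·s).

    Continuous closed form: the rise contributes
    ``peak_delta * (T - rise_tau*(1-e^{-T/rise_tau})) / (1-e^{-T/rise_tau})``
    with ``T`` the onset-to-peak time, and the decay contributes
    ``decay_tau * (peak_delta - band)`` (the tail below the return band is
    cut off, mirroring the measurement's offset rule).
    """
    peak_delta = amplitude_pct * baseline_mean / 100.0
    band = return_band_k * noise_sd
    if peak_delta <= band:
        raise InfeasibleCalibrationError(
            f"peak delta {peak_delta:.4g} does not exceed return band {band:.4g}"
        )
    t_pk = time_to_peak(rise_tau, sampling_interval)
    sat = 1.0 - math.exp(-t_pk / rise_tau)
    rise_int = peak_delta * (t_pk - rise_tau * sat) / sat
    if target_auc <= rise_int:
        raise InfeasibleCalibrationError(
            f"target_auc {target_auc:.4g} is not above the rise-phase integral "
            f"{rise_int:.4g}"
        )
    return (target_auc - rise_int) / (peak_delta - band)


# ---------------------------------------------------------------------------
# cohorts of cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusPreset:
    """Per-stimulus generation settings inside a cohort."""

    responder_fraction: float
    amplitude_pct: float
    concentration_mm: float
    amplitude_cv: float = 0.25
    rise_tau: float = 2.0
    decay_tau: float = 12.0

    def validate(self, name: str = "stimulus") -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ParamValidationError(f"{name}: responder_fraction must be in [0, 1]")
        if self.amplitude_pct < 0:
            raise ParamValidationError(f"{name}: amplitude_pct must be >= 0")
        if self.amplitude_cv < 0:
            raise ParamValidationError(f"{name}: amplitude_cv must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """One diet × sex cohort: which stimuli are applied and at what rates."""

    label: str
    n_cells: int
    stimuli: dict[str, StimulusPreset]
    kcl_positive_fraction: float = 0.35
    kcl_amplitude_pct: float = 40.0
    baseline_mean: float = 1.0
    noise_sd: float = 0.002
    epoch_start_s: float = 30.0
    epoch_duration_s: float = 30.0
    epoch_spacing_s: float = 150.0
    sampling_interval: float = 1.0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ParamValidationError("n_cells must be >= 1")
        if not 0.0 <= self.kcl_positive_fraction <= 1.0:
            raise ParamValidationError("kcl_positive_fraction must be in [0, 1]")
        if not self.stimuli:
            raise ParamValidationError("stimuli must be non-empty")
        for name, preset in self.stimuli.items():
            preset.validate(name)


#: Minimum per-cell amplitude draw, as a fraction of the preset mean; keeps
#: amplitudes positive under the truncated-normal dispersion model.
_AMPLITUDE_FLOOR_FRAC = 0.05


def draw_amplitude(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Per-cell amplitude: Normal(mean, cv*mean) truncated away from zero."""
    if cv == 0 or mean == 0:
        return mean
    return float(max(_AMPLITUDE_FLOOR_FRAC * mean, rng.normal(mean, cv * mean)))


def _cell_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def simulate_cohort(config: CohortConfig, seed: int) -> tuple[list[Trace], pd.DataFrame]:
    """Simulate ``n_cells`` multi-epoch traces and their ground-truth labels.

    Each cell's trace carries one epoch per stimulus in ``config.stimuli``
    (in insertion order) followed by a 50 mM KCl epoch; epochs are spaced so
    the previous response has returned to baseline before the next epoch's
    baseline window opens.  Returns ``(traces, truth)`` where ``truth`` has
    one row per cell × stimulus with columns ``cell_id, group, stimulus,
    is_responder, true_amplitude_pct, kcl_positive``.
    """
    config.validate()
    stim_names = list(config.stimuli) + ["KCL"]
    traces: list[Trace] = []
    rows: list[dict] = []
    for i in range(config.n_cells):
        rng = np.random.default_rng(_cell_seed(seed, i))
        cell_id = f"{config.label}_c{i:04d}"
        kcl_positive = bool(rng.random() < config.kcl_positive_fraction)

        epochs = []
        for j, name in enumerate(stim_names):
            start = config.epoch_start_s + j * config.epoch_spacing_s
            conc = 50.0 if name == "KCL" else config.stimuli[name].concentration_mm
            epochs.append(StimulusEpoch(name, conc, start, start + config.epoch_duration_s))
        total = epochs[-1].end_s + config.epoch_spacing_s

        n = int(round(total / config.sampling_interval))
        times = np.arange(n, dtype=float) * config.sampling_interval
        ratio = config.baseline_mean + rng.normal(0.0, config.noise_sd, size=n)

        for ep in epochs:
            if ep.stimulus == "KCL":
                responds, amp_mean, cv = kcl_positive, config.kcl_amplitude_pct, 0.25
                rise_tau, decay_tau = 1.0, 8.0
            else:
                preset = config.stimuli[ep.stimulus]
                responds = bool(rng.random() < preset.responder_fraction)
                amp_mean, cv = preset.amplitude_pct, preset.amplitude_cv
                rise_tau, decay_tau = preset.rise_tau, preset.decay_tau
            amp = draw_amplitude(rng, amp_mean, cv) if responds else 0.0
            if responds:
                ratio += transient_profile(
                    times, ep.start_s + 2.0,
                    amp * config.baseline_mean / 100.0,
                    rise_tau, decay_tau, config.sampling_interval,
                )
            if ep.stimulus != "KCL":
                rows.append({
                    "cell_id": cell_id, "group": config.label, "stimulus": ep.stimulus,
                    "is_responder": responds, "true_amplitude_pct": amp,
                    "kcl_positive": kcl_positive,
                })
        traces.append(Trace(cell_id=cell_id, time=times, ratio=ratio, epochs=epochs))
    return traces, pd.DataFrame(rows)


def simulate_preset_traces(
    params: TraceGenParams,
    n: int,
    seed: int,
    amplitude_cv: float = 0.25,
) -> tuple[list[Trace], np.ndarray]:
    """``n`` responsive single-epoch traces with per-cell amplitude dispersion.

    Amplitudes are drawn per cell as Normal(params.amplitude_pct, cv·mean),
    truncated away from zero; returns the traces and the drawn true
    amplitudes (%).
    """
    params.validate()
    traces, amps = [], np.empty(n)
    for i in range(n):
        ss = _cell_seed(seed, i)
        rng = np.random.default_rng(ss)
        amp = draw_amplitude(rng, params.amplitude_pct, amplitude_cv)
        amps[i] = amp
        tr = simulate_trace(replace(params, amplitude_pct=amp, responder=True), rng)
        tr.cell_id = f"cell{i:04d}"
        traces.append(tr)
    return traces, amps


# ---------------------------------------------------------------------------
# two-bottle intake records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntakeGenParams:
    """Two-bottle preference test generator for one group × stimulus.

    ``true_preference`` is the expected share of total intake taken from the
    test bottle over 48 h; either one probability for all concentrations or a
    per-concentration mapping.  Animal-to-animal variation follows a Beta
    distribution with concentration ``animal_noise_kappa`` (None disables it).
    ``side_bias`` shifts each 24 h period's test share toward the animal's
    preferred bottle side; the 24 h side swap is what cancels it.
    """

    group: str
    stimulus: str
    concentrations_mm: tuple[float, ...]
    true_preference: float | dict[float, float] = 0.5
    n_animals: int = 5
    daily_total_mean: float = 6.0
    daily_total_sd: float = 1.0
    n_periods: int = 2
    animal_noise_kappa: float | None = 50.0
    side_bias: float = 0.0

    def validate(self) -> None:
        if not self.daily_total_mean > 0:
            raise ParamValidationError("daily_total_mean must be > 0")
        if self.daily_total_sd < 0:
            raise ParamValidationError("daily_total_sd must be >= 0")
        if self.n_animals < 1:
            raise ParamValidationError("n_animals must be >= 1")
        if self.n_periods < 1:
            raise ParamValidationError("n_periods must be >= 1")
        prefs = (self.true_preference.values()
                 if isinstance(self.true_preference, dict) else [self.true_preference])
        for p in prefs:
            if not 0.0 <= p <= 1.0:
                raise ParamValidationError("true_preference must be in [0, 1]")

    def preference_at(self, conc: float) -> float:
        if isinstance(self.true_preference, dict):
            return self.true_preference[conc]
        return self.true_preference


def simulate_preference_records(params: IntakeGenParams, seed: int) -> pd.DataFrame:
    """Intake table: one row per animal × concentration × 24 h period.

    Columns: ``animal_id, group, stimulus, concentration_mM, period,
    test_side, test_intake_ml, water_intake_ml``.  The test bottle starts on
    alternating sides across animals and swaps sides every period.
    """
    params.validate()
    rows = []
    for a in range(params.n_animals):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1000, a))
        )
        animal_id = f"{params.group}_m{a:02d}"
        start_left = a % 2 == 0
        for conc in params.concentrations_mm:
            p = params.preference_at(conc)
            if params.animal_noise_kappa and 0.0 < p < 1.0:
                k = params.animal_noise_kappa
                p_animal = float(rng.beta(k * p, k * (1.0 - p)))
            else:
                p_animal = p
            for period in range(1, params.n_periods + 1):
                total = max(0.0, rng.normal(params.daily_total_mean,
                                            params.daily_total_sd))
                test_on_left = start_left if period % 2 == 1 else not start_left
                # the animal's (side_bias) preferred side is 'left'
                share = np.clip(
                    p_animal + (params.side_bias if test_on_left else -params.side_bias),
                    0.0, 1.0,
                )
                test = total * share
                rows.append({
                    "animal_id": animal_id, "group": params.group,
                    "stimulus": params.stimulus, "concentration_mM": conc,
                    "period": period,
                    "test_side": "left" if test_on_left else "right",
                    "test_intake_ml": test, "water_intake_ml": total - test,
                })
    return pd.DataFrame(rows)
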