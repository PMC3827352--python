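"""Trace-level quantification of taste-evoked calcium responses.

The response definition follows the classic baseline-SD rule used in
ratiometric taste-cell imaging: a cell is scored responsive to a stimulus if
its F340/F380 ratio rises more than two standard deviations above the
pre-stimulus baseline (here: for at least ``min_run`` consecutive samples,
to keep single noise spikes from qualifying).  For responsive cells the
pipeline reports

* amplitude as a percentage over baseline, ``100 * (peak - baseline) / baseline``,
* the response window from the initial departure from baseline (onset) until
  the ratio settles back within ``± return_band_k`` baseline SDs (offset),
* the trapezoidal integral of the supra-baseline ratio over that window
  (AUC, ratio·s), and
* duration = offset − onset.

Responses that never return to baseline before the recording ends are
flagged ``excluded_no_return``: they keep their amplitude but are excluded
from AUC and duration summaries (configurable policy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trace import StimulusEpoch, Trace, TraceValidationError

logger = logging.getLogger(__name__)

#: Detection threshold, in baseline SDs above the baseline mean.
DETECTION_K = 2.0


class DataError(ValueError):
    """Input data violates a quantification precondition."""


@dataclass(frozen=True)
class BaselineStats:
    """Pre-stimulus baseline: mean and sample SD over a window."""

    mean: float
    sd: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DataError("baseline sd must be >= 0")


@dataclass(frozen=True)
class QuantConfig:
    """Tunable thresholds of the quantification stage.

    All values configurable; defaults are the package's operating point:
    30 s baseline window, 2-SD threshold sustained for min_run=3 samples,
    detection window extended post_window_s=60 s past stimulus washout,
    return band of ±2 baseline SDs held for return_run=3 samples (run length
    chosen by a bias study of the offset estimator; see docs/methods.md).
    """

    baseline_window_s: float = 30.0
    min_run: int = 3
    post_window_s: float = 60.0
    return_band_k: float = 2.0
    return_run: int = 3
    smooth: bool = False  # optional 3-point moving average before peak search
    exclude_no_return_everywhere: bool = False


DEFAULT_CONFIG = QuantConfig()


@dataclass
class ResponseCall:
    """Per cell × stimulus quantification result."""

    cell_id: str
    stimulus: str
    concentration_mm: float
    responsive: bool
    baseline: BaselineStats
    peak: float | None = None
    amplitude_pct: float | None = None
    onset_s: float | None = None
    offset_s: float | None = None
    auc: float | None = None
    duration_s: float | None = None
    excluded_no_return: bool = False


# ---------------------------------------------------------------------------
# ratiometry and baseline
# ---------------------------------------------------------------------------

def compute_ratio(trace: Trace) -> Trace:
    """Samplewise F340/F380; passthrough if the ratio is already present."""
    if trace.ratio is not None:
        return trace
    bad = np.flatnonzero(trace.f380 <= 0)
    if bad.size:
        raise DataError(f"f380 <= 0 at sample index {int(bad[0])}")
    return trace.with_ratio(trace.f340 / trace.f380)


def _ratio(trace: Trace) -> np.ndarray:
    if trace.ratio is None:
        raise DataError("trace has no ratio channel; call compute_ratio first")
    return trace.ratio


#: Floor substituted for a zero baseline SD (noise-free synthetic input) so
#: the 2-SD threshold remains defined.
_SD_FLOOR_EPS = 1e-9


def estimate_baseline(
    trace: Trace, epoch: StimulusEpoch, window_s: float = 30.0, min_samples: int = 5
) -> BaselineStats:
    """Mean and sample SD (n−1) of the ratio over the ``window_s`` seconds
    immediately preceding the stimulus epoch.

    ``min_samples`` guards against windows too short for a stable SD; lower
    it only for hand-constructed inputs.
    """
    start = epoch.start_s - window_s
    if start < trace.time[0] - 1e-9:
        raise DataError(
            f"baseline window [{start:.6g}, {epoch.start_s:.6g}) starts before the trace"
        )
    r = _ratio(trace)
    mask = (trace.time >= start - 1e-9) & (trace.time < epoch.start_s - 1e-9)
    vals = r[mask]
    if vals.size < max(min_samples, 2):
        raise DataError(
            f"only {vals.size} pre-stimulus samples in baseline window "
            f"(need >= {max(min_samples, 2)})"
        )
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        sd = _SD_FLOOR_EPS * max(1.0, abs(mean))
    return BaselineStats(mean=mean, sd=sd, window=(start, epoch.start_s))


# ---------------------------------------------------------------------------
# detection and response-window localisation
# ---------------------------------------------------------------------------

def _first_run(mask: np.ndarray, run: int) -> int | None:
    """Index (into mask) of the first run of >= ``run`` consecutive True."""
    if run <= 0:
        raise ValueError("run length must be positive")
    count = 0
    for i, m in enumerate(mask):
        count = count + 1 if m else 0
        if count >= run:
            return i - run + 1
    return None


def detect_response(
    trace: Trace,
    epoch: StimulusEpoch,
    baseline: BaselineStats,
    min_run: int = DEFAULT_CONFIG.min_run,
    post_window_s: float = DEFAULT_CONFIG.post_window_s,
) -> tuple[bool, int | None]:
    """2-SD threshold rule: responsive iff >= ``min_run`` consecutive samples
    within [epoch start, epoch end + post_window_s] exceed
    ``baseline.mean + 2 * baseline.sd``.

    Returns ``(responsive, crossing_index)`` with the index absolute into the
    trace (first sample of the qualifying run).
    """
    r = _ratio(trace)
    lo = trace.index_at(epoch.start_s)
    hi = trace.index_at(min(epoch.end_s + post_window_s, trace.time[-1]))
    window = r[lo : hi + 1]
    if window.size == 0:
        logger.warning("%s: empty detection window for %s", trace.cell_id, epoch.stimulus)
        return False, None
    above = window > baseline.mean + DETECTION_K * baseline.sd
    start = _first_run(above, min_run)
    if start is None:
        return False, None
    return True, lo + start


def locate_response_window(
    trace: Trace,
    baseline: BaselineStats,
    crossing_index: int,
    return_band_k: float = DEFAULT_CONFIG.return_band_k,
    return_run: int = DEFAULT_CONFIG.return_run,
) -> tuple[float, float | None, bool]:
    """Onset/offset of a detected response.

    Onset: time of the last sample at or below the baseline mean preceding
    the qualifying run (the initial departure from baseline).  Offset: first
    post-peak time from which the ratio stays within
    ``baseline.mean ± return_band_k * baseline.sd`` for >= ``return_run``
    consecutive samples.  Returns ``(onset_s, offset_s, no_return)``;
    ``offset_s`` is None when the trace ends before returning.
    """
    r = _ratio(trace)
    below = np.flatnonzero(r[:crossing_index] <= baseline.mean)
    onset_idx = int(below[-1]) if below.size else 0
    peak_idx = crossing_index + int(np.argmax(r[crossing_index:]))
    band = return_band_k * baseline.sd
    tail = r[peak_idx + 1 :]
    inside = np.abs(tail - baseline.mean) <= band
    # offset = first sample of a return_run-long within-band run
    start = _first_run(inside, return_run)
    if start is None:
        return float(trace.time[onset_idx]), None, True
    offset_idx = peak_idx + 1 + start
    return float(trace.time[onset_idx]), float(trace.time[offset_idx]), False


# ---------------------------------------------------------------------------
# amplitude, AUC, duration
# ---------------------------------------------------------------------------

def _window_slice(trace: Trace, onset_s: float, offset_s: float | None) -> slice:
    lo = trace.index_at(onset_s)
    hi = trace.n_samples - 1 if offset_s is None else trace.index_at(offset_s)
    return slice(lo, hi + 1)


def quantify_amplitude(
    trace: Trace,
    baseline: BaselineStats,
    onset_s: float,
    offset_s: float | None = None,
    smooth: bool = False,
) -> tuple[float, float]:
    """Peak ratio in [onset, offset] (trace end when no return) and the
    amplitude ``100 * (peak - baseline.mean) / baseline.mean`` in percent.

    With ``smooth`` the peak is read from a 3-point moving average
    (documented as altering amplitudes; off by default).
    """
    if baseline.mean <= 0:
        raise DataError("baseline mean must be positive for percent amplitude")
    r = _ratio(trace)
    if smooth:
        r = np.convolve(r, np.ones(3) / 3.0, mode="same")
    window = r[_window_slice(trace, onset_s, offset_s)]
    peak = float(np.max(window))
    return peak, 100.0 * (peak - baseline.mean) / baseline.mean


def integrate_response(
    trace: Trace, baseline: BaselineStats, onset_s: float, offset_s: float
) -> float:
    """Trapezoidal integral of ``max(ratio - baseline.mean, 0)`` over
    [onset_s, offset_s] (ratio·s)."""
    if offset_s <= onset_s:
        raise DataError(f"offset {offset_s} must follow onset {onset_s}")
    sl = _window_slice(trace, onset_s, offset_s)
    excess = np.maximum(_ratio(trace)[sl] - baseline.mean, 0.0)
    return float(np.trapezoid(excess, trace.time[sl]))


# ---------------------------------------------------------------------------
# per-cell composition
# ---------------------------------------------------------------------------

def quantify_epoch(
    trace: Trace, epoch: StimulusEpoch, config: QuantConfig = DEFAULT_CONFIG
) -> ResponseCall:
    """Full quantification of one epoch using its immediately-preceding
    baseline window."""
    baseline = estimate_baseline(trace, epoch, config.baseline_window_s)
    responsive, crossing = detect_response(
        trace, epoch, baseline, config.min_run, config.post_window_s
    )
    call = ResponseCall(
        cell_id=trace.cell_id,
        stimulus=epoch.stimulus,
        concentration_mm=epoch.concentration_mm,
        responsive=responsive,
        baseline=baseline,
    )
    if not responsive:
        return call
    onset, offset, no_return = locate_response_window(
        trace, baseline, crossing, config.return_band_k, config.return_run
    )
    call.onset_s = onset
    call.offset_s = offset
    call.excluded_no_return = no_return
    call.peak, call.amplitude_pct = quantify_amplitude(
        trace, baseline, onset, offset, config.smooth
    )
    if no_return:
        logger.info(
            "%s/%s: response did not return to baseline; excluded from "
            "AUC/duration summaries", trace.cell_id, epoch.stimulus,
        )
    else:
        call.auc = integrate_response(trace, baseline, onset, offset)
        call.duration_s = offset - onset
    return call


def quantify_cell(trace: Trace, config: QuantConfig = DEFAULT_CONFIG) -> list[ResponseCall]:
    """One :class:`ResponseCall` per epoch, each scored independently against
    its own pre-stimulus baseline."""
    trace = compute_ratio(trace)
    if not trace.epochs:
        raise DataError(f"{trace.cell_id}: trace has no stimulus epochs")
    epochs = sorted(trace.epochs, key=lambda e: e.start_s)
    for prev, nxt in zip(epochs, epochs[1:]):
        if nxt.start_s < prev.end_s:
            raise TraceValidationError(
                f"{trace.cell_id}: epochs {prev.stimulus} and {nxt.stimulus} overlap"
            )
    return [quantify_epoch(trace, ep, config) for ep in epochs]
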