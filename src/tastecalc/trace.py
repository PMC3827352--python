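"""Core containers for single-cell fura-2 recordings.

A :class:`Trace` holds one cell's time series — either the two raw
excitation channels (340 nm and 380 nm) or the precomputed dimensionless
F340/F380 ratio — together with the stimulus epochs applied during the
recording.  Time is in seconds, trace-local (zero at the first frame), on a
uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Stimuli used throughout: saccharin and acesulfame K (sweet), monopotassium
#: glutamate (umami), denatonium benzoate (bitter), KCl (depolarising control).
KNOWN_STIMULI = ("SAC", "ACEK", "MPG", "DEN", "KCL")

_SPACING_RTOL = 1e-6


class TraceValidationError(ValueError):
    """A trace or epoch violates a structural invariant."""


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus application window on a trace's local clock."""

    stimulus: str
    concentration_mm: float
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise TraceValidationError(
                f"epoch start_s ({self.start_s}) must precede end_s ({self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Trace:
    """One cell's recording: uniform time grid plus channel(s) and epochs.

    Either ``ratio`` or both ``f340`` and ``f380`` must be present; the
    ratio channel is derived lazily by :func:`tastecalc.quantify.compute_ratio`.
    """

    cell_id: str
    time: np.ndarray
    f340: np.ndarray | None = None
    f380: np.ndarray | None = None
    ratio: np.ndarray | None = None
    epochs: list[StimulusEpoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("f340", "f380", "ratio"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if arr.shape != self.time.shape:
                    raise TraceValidationError(
                        f"{name} length {arr.shape} does not match time {self.time.shape}"
                    )
                setattr(self, name, arr)
        if self.time.ndim != 1 or self.time.size < 2:
            raise TraceValidationError("trace needs at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise TraceValidationError("time must be strictly increasing")
        if np.any(np.abs(dt - dt[0]) > _SPACING_RTOL * max(abs(dt[0]), 1.0)):
            raise TraceValidationError("time grid must be uniformly spaced")
        if self.ratio is None and (self.f340 is None or self.f380 is None):
            raise TraceValidationError(
                "trace needs either a ratio channel or both f340 and f380"
            )
        for ep in self.epochs:
            if ep.start_s < self.time[0] or ep.end_s > self.time[-1]:
                raise TraceValidationError(
                    f"epoch {ep.stimulus} [{ep.start_s}, {ep.end_s}] outside trace span"
                )

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def with_ratio(self, ratio: np.ndarray) -> "Trace":
        return replace(self, ratio=np.asarray(ratio, dtype=float))

    def index_at(self, t: float) -> int:
        """Index of the first sample at or after time ``t``."""
        return int(np.searchsorted(self.time, t - _SPACING_RTOL))
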