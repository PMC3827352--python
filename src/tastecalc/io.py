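"""CSV/YAML schemas shared by the generator, the pipeline and the CLI.

Traces travel as a long-format table (``cell_id, time_s`` plus either
``ratio`` or ``f340``/``f380``) with a sidecar epochs table (``cell_id,
stimulus, concentration_mM, start_s, end_s``).  Response calls, ground
truth and intake records are plain tidy CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .quantify import BaselineStats, ResponseCall
from .trace import StimulusEpoch, Trace

TRACE_COLUMNS = ("cell_id", "time_s")
EPOCH_COLUMNS = ("cell_id", "stimulus", "concentration_mM", "start_s", "end_s")


def traces_to_frames(traces: Iterable[Trace]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format trace table and sidecar epoch table."""
    trace_rows, epoch_rows = [], []
    for tr in traces:
        df = pd.DataFrame({"cell_id": tr.cell_id, "time_s": tr.time})
        if tr.ratio is not None:
            df["ratio"] = tr.ratio
        else:
            df["f340"] = tr.f340
            df["f380"] = tr.f380
        trace_rows.append(df)
        for ep in tr.epochs:
            epoch_rows.append({
                "cell_id": tr.cell_id, "stimulus": ep.stimulus,
                "concentration_mM": ep.concentration_mm,
                "start_s": ep.start_s, "end_s": ep.end_s,
            })
    return pd.concat(trace_rows, ignore_index=True), pd.DataFrame(epoch_rows)


def write_traces(traces: Iterable[Trace], trace_path: Path, epoch_path: Path) -> None:
    tdf, edf = traces_to_frames(traces)
    tdf.to_csv(trace_path, index=False)
    edf.to_csv(epoch_path, index=False)


def read_traces(trace_path: Path, epoch_path: Path) -> list[Trace]:
    """Reconstruct :class:`Trace` objects from the long-format CSV pair."""
    tdf = pd.read_csv(trace_path)
    edf = pd.read_csv(epoch_path)
    for col in TRACE_COLUMNS:
        if col not in tdf.columns:
            raise ValueError(f"trace table missing column {col!r}")
    for col in EPOCH_COLUMNS:
        if col not in edf.columns:
            raise ValueError(f"epoch table missing column {col!r}")
    epochs_by_cell: dict[str, list[StimulusEpoch]] = {}
    for rec in edf.to_dict("records"):
        epochs_by_cell.setdefault(str(rec["cell_id"]), []).append(
            StimulusEpoch(str(rec["stimulus"]), float(rec["concentration_mM"]),
                          float(rec["start_s"]), float(rec["end_s"]))
        )
    traces = []
    for cell_id, sub in tdf.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_s")
        kwargs: dict = {}
        if "ratio" in sub.columns and sub["ratio"].notna().all():
            kwargs["ratio"] = sub["ratio"].to_numpy()
        else:
            kwargs["f340"] = sub["f340"].to_numpy()
            kwargs["f380"] = sub["f380"].to_numpy()
        traces.append(Trace(
            cell_id=str(cell_id), time=sub["time_s"].to_numpy(),
            epochs=epochs_by_cell.get(str(cell_id), []), **kwargs,
        ))
    return traces


def calls_to_frame(calls: Iterable[ResponseCall]) -> pd.DataFrame:
    """One row per cell × stimulus with every quantified field."""
    rows = []
    for c in calls:
        rows.append({
            "cell_id": c.cell_id, "stimulus": c.stimulus,
            "concentration_mM": c.concentration_mm, "responsive": c.responsive,
            "baseline_mean": c.baseline.mean, "baseline_sd": c.baseline.sd,
            "peak": c.peak, "amplitude_pct": c.amplitude_pct,
            "onset_s": c.onset_s, "offset_s": c.offset_s,
            "auc": c.auc, "duration_s": c.duration_s,
            "excluded_no_return": c.excluded_no_return,
        })
    return pd.DataFrame(rows)


def frame_to_calls(df: pd.DataFrame) -> list[ResponseCall]:
    calls = []
    for rec in df.to_dict("records"):
        def _opt(key: str) -> float | None:
            v = rec.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        calls.append(ResponseCall(
            cell_id=str(rec["cell_id"]), stimulus=str(rec["stimulus"]),
            concentration_mm=float(rec["concentration_mM"]),
            responsive=bool(rec["responsive"]),
            baseline=BaselineStats(float(rec["baseline_mean"]),
                                   float(rec["baseline_sd"]), (np.nan, np.nan)),
            peak=_opt("peak"), amplitude_pct=_opt("amplitude_pct"),
            onset_s=_opt("onset_s"), offset_s=_opt("offset_s"),
            auc=_opt("auc"), duration_s=_opt("duration_s"),
            excluded_no_return=bool(rec.get("excluded_no_return", False)),
        ))
    return calls


def load_yaml(path: Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return data


def dump_yaml(data: dict, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
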