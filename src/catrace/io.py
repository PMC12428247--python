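"""Trace container and the long/tidy CSV formats shared by all stages.

The on-disk trace format is one row per (cell, frame):

``cell_id,line_id,group,stage,replicate_id,stimulus,time_s,intensity[,background]``

UTF-8, '.' decimal separator, times in seconds on the protocol grid.
Reports are a single tidy CSV mixing summary rows (one per
stage x stimulus x metric x group) and test rows (one per comparison),
with a JSON sidecar holding the configuration and seeds that produced them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .protocol import StimulusProtocol

TRACE_COLUMNS = [
    "cell_id",
    "line_id",
    "group",
    "stage",
    "replicate_id",
    "stimulus",
    "time_s",
    "intensity",
]


@dataclass
class Trace:
    """Raw per-cell fluorescence series with cohort labels.

    ``background`` is either a scalar offset, a per-frame array, or None when
    no background estimate accompanies the recording.
    """

    cell_id: str
    line_id: str
    group: str
    stage: str
    replicate_id: str
    stimulus: str
    times: np.ndarray
    raw: np.ndarray
    background: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.times.shape != self.raw.shape:
            raise ValidationError(
                f"{self.cell_id}: times and raw must have equal length"
            )
        if self.times.size == 0:
            raise ValidationError(f"{self.cell_id}: empty trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.cell_id}: times must be strictly increasing")
        if isinstance(self.background, np.ndarray) and (
            self.background.shape != self.raw.shape
        ):
            raise ValidationError(
                f"{self.cell_id}: per-frame background must match trace length"
            )

    @property
    def replicate_key(self) -> str:
        """Replicate identity used for replicate-level statistics."""
        return f"{self.line_id}/{self.replicate_id}"


def _validate_grid(times: np.ndarray, protocol: StimulusProtocol, cell_id: str) -> None:
    dt = protocol.frame_interval
    gaps = np.diff(times)
    if np.any(gaps > 1.5 * dt):
        raise ValidationError(f"{cell_id}: time gap exceeds 1.5x frame interval")
    expected = np.round(times / dt) * dt
    if np.any(np.abs(times - expected) > dt / 2):
        raise ValidationError(f"{cell_id}: times off the protocol grid")


def read_traces(path: str | Path, protocol: StimulusProtocol) -> list[Trace]:
    """Read a long trace CSV, returning one Trace per cell.

    Times are validated against the protocol grid to within half a frame
    interval; gaps larger than 1.5x the frame interval are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty trace file") from None
    required = {"cell_id", "line_id", "group", "stage", "replicate_id", "time_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no trace rows")
    has_bg = "background" in df.columns
    has_stim = "stimulus" in df.columns
    traces: list[Trace] = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        times = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"{cell_id}: non-monotone times")
        _validate_grid(times, protocol, str(cell_id))
        background: float | np.ndarray | None = None
        if has_bg:
            bg = sub["background"].to_numpy(dtype=float)
            if np.all(np.isnan(bg)):
                background = None
            elif np.unique(bg[~np.isnan(bg)]).size == 1:
                background = float(bg[~np.isnan(bg)][0])
            else:
                background = bg
        traces.append(
            Trace(
                cell_id=str(cell_id),
                line_id=str(sub["line_id"].iloc[0]),
                group=str(sub["group"].iloc[0]),
                stage=str(sub["stage"].iloc[0]),
                replicate_id=str(sub["replicate_id"].iloc[0]),
                stimulus=str(sub["stimulus"].iloc[0]) if has_stim else protocol.stimulus_name,
                times=times,
                raw=sub["intensity"].to_numpy(dtype=float),
                background=background,
            )
        )
    return traces


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    """Long/tidy DataFrame view of a trace collection."""
    parts = []
    for tr in traces:
        d = {
            "cell_id": tr.cell_id,
            "line_id": tr.line_id,
            "group": tr.group,
            "stage": tr.stage,
            "replicate_id": tr.replicate_id,
            "stimulus": tr.stimulus,
            "time_s": tr.times,
            "intensity": tr.raw,
        }
        if tr.background is not None:
            d["background"] = np.broadcast_to(
                np.asarray(tr.background, dtype=float), tr.raw.shape
            )
        parts.append(pd.DataFrame(d))
    return pd.concat(parts, ignore_index=True)


def write_traces(traces: Sequence[Trace], path: str | Path) -> Path:
    if not traces:
        raise ValidationError("refusing to write an empty trace collection")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traces_to_frame(traces).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Comparison reports
# ---------------------------------------------------------------------------

def write_report(results: Iterable, path: str | Path, config: dict | None = None) -> Path:
    """Write comparison results to a tidy CSV plus a JSON config sidecar.

    One ``row_type="summary"`` row per (stage, stimulus, metric, group) with
    mean/sem/n, and one ``row_type="test"`` row per comparison with the
    Mann-Whitney U and two-tailed p.
    """
    results = list(results)
    if not results:
        raise ValidationError("refusing to write an empty report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for res in results:
        for gs in res.summaries:
            rows.append(
                {
                    "row_type": "summary",
                    "stage": res.stage,
                    "stimulus": res.stimulus,
                    "metric": res.metric,
                    "group": gs.group,
                    "mean": gs.mean,
                    "sem": gs.sem,
                    "n": gs.n,
                    "sem_unit": gs.sem_unit,
                    "U": np.nan,
                    "p_two_tailed": np.nan,
                    "test_unit": "",
                }
            )
        rows.append(
            {
                "row_type": "test",
                "stage": res.stage,
                "stimulus": res.stimulus,
                "metric": res.metric,
                "group": " vs ".join(gs.group for gs in res.summaries),
                "mean": np.nan,
                "sem": np.nan,
                "n": sum(res.n_per_group),
                "sem_unit": "",
                "U": res.U,
                "p_two_tailed": res.p_two_tailed,
                "test_unit": res.test_unit,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"config": config or {}, "n_comparisons": len(results)}
    sidecar.write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "row_type" not in df.columns:
        raise FormatError(f"{path}: not a catrace report")
    return df


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
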