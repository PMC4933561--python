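"""Shared in-memory containers and their on-disk formats.

Two containers travel through nearly every stage of the pipeline:

``Timecourse``
    A stimulus-locked scalar signal — vessel diameter in micrometres or
    percent diameter change — sampled at a fixed rate, with the location
    metadata (subject, vessel, cortical depth, trunk/branch, condition)
    needed for cohort-level statistics.  Time is expressed relative to
    stimulus onset, so ``t < 0`` is the pre-stimulus baseline.

``LineScanImage``
    A lines x pixels space-time image produced by repeatedly scanning a
    single trajectory, either across a fluorescently labelled vessel
    lumen or along a row of neuronal somata.  Stored as single-channel
    TIFF with a JSON sidecar carrying the scan metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass
class Timecourse:
    """A sampled scalar signal locked to stimulus onset (t = 0 s)."""

    time: np.ndarray            # seconds relative to stimulus onset
    value: np.ndarray           # percent change, or um when units == "um"
    units: str = "pct"          # "pct" | "um"
    depth_um: float = float("nan")
    subject_id: str = ""
    vessel_id: str = ""
    branch: str = "trunk"       # "trunk" | "branch"
    condition: str = "control"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must have identical shapes")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds (median of successive differences)."""
        if self.time.size < 2:
            raise ValueError("need at least two samples to define dt")
        return float(np.median(np.diff(self.time)))

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def with_value(self, value: np.ndarray, units: str | None = None) -> "Timecourse":
        """Copy of this trace with a new value array (metadata preserved)."""
        return replace(self, value=np.asarray(value, dtype=float),
                       units=self.units if units is None else units)

    def pre_stimulus_mask(self) -> np.ndarray:
        return self.time < 0.0


@dataclass
class LineScanImage:
    """Repeated line scans: ``data[line, pixel]`` intensities (>= 0)."""

    data: np.ndarray
    line_period_s: float
    pixel_size_um: float
    stim_onset_line: int = 0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("line-scan data must be 2-D (lines x pixels)")
        if self.line_period_s <= 0:
            raise ValueError("line_period_s must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    def line_times(self) -> np.ndarray:
        """Time of each line relative to stimulus onset, in seconds."""
        return (np.arange(self.n_lines) - self.stim_onset_line) * self.line_period_s


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

_TC_COLUMNS = ["subject", "vessel", "depth_um", "time_s", "value_pct"]


def timecourses_to_csv(traces: Iterable[Timecourse], path: str | Path) -> None:
    """Write a collection of traces as long-format CSV.

    Columns: subject, vessel, depth_um, time_s, value_pct (plus branch,
    condition, units kept for round-tripping).
    """
    frames = []
    for tc in traces:
        frames.append(pd.DataFrame({
            "subject": tc.subject_id,
            "vessel": tc.vessel_id,
            "depth_um": tc.depth_um,
            "time_s": tc.time,
            "value_pct": tc.value,
            "branch": tc.branch,
            "condition": tc.condition,
            "units": tc.units,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def timecourses_from_csv(path: str | Path) -> list[Timecourse]:
    df = pd.read_csv(path)
    missing = [c for c in _TC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"timecourse CSV missing columns: {missing}")
    out: list[Timecourse] = []
    keys = ["subject", "vessel", "depth_um"]
    for (subject, vessel, depth), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_s")
        out.append(Timecourse(
            time=grp["time_s"].to_numpy(),
            value=grp["value_pct"].to_numpy(),
            units=str(grp["units"].iloc[0]) if "units" in grp else "pct",
            depth_um=float(depth),
            subject_id=str(subject),
            vessel_id=str(vessel),
            branch=str(grp["branch"].iloc[0]) if "branch" in grp else "trunk",
            condition=str(grp["condition"].iloc[0]) if "condition" in grp else "control",
        ))
    return out


def linescan_to_tiff(img: LineScanImage, path: str | Path) -> None:
    """Single-channel TIFF plus ``<stem>.json`` metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, img.data.astype(np.float32))
    sidecar = {
        "line_period_s": img.line_period_s,
        "pixel_size_um": img.pixel_size_um,
        "stim_onset_line": int(img.stim_onset_line),
        "channel_label": img.channel_label,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def linescan_from_tiff(path: str | Path) -> LineScanImage:
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return LineScanImage(
        data=np.asarray(data, dtype=float),
        line_period_s=float(meta["line_period_s"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        stim_onset_line=int(meta.get("stim_onset_line", 0)),
        channel_label=str(meta.get("channel_label", "")),
    )
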