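"""Interchange tables between the simulator/generator and the analysis stages.

Two plain-CSV dialects are used throughout:

* ``TrackTable`` — trajectory rows ``track_id, t, x, y[, z]`` (s, μm) from
  homogeneous tracking assays, at a uniform frame interval.
* ``SnapshotSeries`` — time-lapse rows ``replicate, t, x`` of in-channel
  positions from race assays, one snapshot every few minutes.

Both carry a metadata dictionary (frame interval, localization noise,
generator ground truth, geometry, seeds) written as a JSON sidecar so the
CSV stays a plain table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = ["TrackTable", "SnapshotSeries"]

_FLOAT_FMT = "%.6f"


@dataclass
class TrackTable:
    """Trajectory table with one row per (track, frame)."""

    frames: pd.DataFrame
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"track_id", "t", "x", "y"}
        missing = required - set(self.frames.columns)
        if missing:
            raise ValueError(f"TrackTable missing columns: {sorted(missing)}")

    @property
    def has_z(self) -> bool:
        return "z" in self.frames.columns

    @property
    def frame_dt(self) -> float:
        if "frame_dt" in self.metadata:
            return float(self.metadata["frame_dt"])
        t = self.frames[self.frames.track_id == self.frames.track_id.iloc[0]]["t"]
        return float(np.median(np.diff(t.to_numpy())))

    @property
    def n_tracks(self) -> int:
        return int(self.frames["track_id"].nunique())

    def groupby_track(self):
        return self.frames.groupby("track_id", sort=True)

    def to_csv(self, path) -> None:
        path = Path(path)
        self.frames.to_csv(path, index=False, float_format=_FLOAT_FMT)
        if self.metadata:
            path.with_suffix(".meta.json").write_text(
                json.dumps(self.metadata, indent=2, sort_keys=True) + "\n"
            )

    @classmethod
    def from_csv(cls, path) -> "TrackTable":
        path = Path(path)
        meta_path = path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(pd.read_csv(path), meta)


@dataclass
class SnapshotSeries:
    """Positions of all in-channel bacteria at each snapshot time, one replicate."""

    replicate: int
    times: np.ndarray  # (n_times,) s
    positions: List[np.ndarray]  # per time, x positions (μm), unsorted
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("one position array is required per snapshot time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        self.positions = [np.asarray(p, dtype=float) for p in self.positions]

    def counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.positions])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.replicate, t, x)
            for t, pos in zip(self.times, self.positions)
            for x in pos
        ]
        return pd.DataFrame(rows, columns=["replicate", "t", "x"])

    @staticmethod
    def write_csv(series: List["SnapshotSeries"], path) -> None:
        path = Path(path)
        df = pd.concat([s.to_frame() for s in series], ignore_index=True)
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        meta = {str(s.replicate): s.metadata for s in series if s.metadata}
        # empty snapshots disappear from long-format rows; keep the time grid
        meta["_times"] = [float(t) for t in series[0].times]
        path.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )

    @staticmethod
    def read_csv(path, times: Optional[np.ndarray] = None) -> List["SnapshotSeries"]:
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        if times is None:
            times = np.array(meta.get("_times", sorted(df["t"].unique())), dtype=float)
        out = []
        for rep, grp in df.groupby("replicate", sort=True):
            by_t = {t: g["x"].to_numpy() for t, g in grp.groupby("t")}
            pos = [by_t.get(t, np.empty(0)) for t in times]
            out.append(
                SnapshotSeries(int(rep), times, pos, meta.get(str(int(rep)), {}))
            )
        return out
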