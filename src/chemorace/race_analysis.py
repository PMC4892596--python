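"""Front-progression statistics for channel race assays.

Quantifies gradient climbing the way the microfluidic assay does:

* the *progression function* N(x, t) — the number of bacteria located
  between position x and the reservoir end of the channel;
* *rank-k fronts* x_k(t) — the position of the k-th most advanced
  bacterium (k = 10, 20, 40), undefined while fewer than k are present;
* early-window least-squares slopes of x_k(t) (the front speed during the
  initial, approximately linear phase);
* replicate averaging with the standard error of the mean;
* saturation detection (late-window slope collapsing relative to the
  early window), the signature of the stationary density profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .tables import SnapshotSeries

__all__ = [
    "ProgressionCurve",
    "FrontTrajectory",
    "SlopeEstimate",
    "progression_function",
    "front_position",
    "front_trajectory",
    "fit_front_slope",
    "replicate_mean",
    "saturation_check",
]


@dataclass
class ProgressionCurve:
    """Counts N(x, t) of bacteria at positions >= x, per snapshot time."""

    x: np.ndarray  # (nx,)
    times: np.ndarray  # (nt,)
    N: np.ndarray  # (nt, nx)


@dataclass
class FrontTrajectory:
    """Rank-k front positions over time; NaN marks 'fewer than k present'."""

    k: int
    times: np.ndarray
    x_k: np.ndarray

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.x_k)


@dataclass
class SlopeEstimate:
    """OLS front slope (μm/s) with standard error and fit window."""

    slope: float
    se: float
    window: Tuple[float, float]
    n_points: int


def progression_function(
    snapshots: SnapshotSeries, x_grid: Optional[np.ndarray] = None,
    L: float = 4000.0, dx: float = 25.0,
) -> ProgressionCurve:
    """N(x, t) = number of positions >= x, evaluated on a grid (default 25 μm)."""
    if x_grid is None:
        x_grid = np.arange(0.0, L + dx / 2, dx)
    x_grid = np.asarray(x_grid, dtype=float)
    N = np.empty((len(snapshots.times), len(x_grid)))
    for i, pos in enumerate(snapshots.positions):
        s = np.sort(pos)
        N[i] = len(s) - np.searchsorted(s, x_grid, side="left")
    return ProgressionCurve(x_grid, snapshots.times, N)


def front_position(positions: np.ndarray, k: int) -> float:
    """Position of the k-th most advanced bacterium; NaN when count < k.

    Ties share the value: the k-th largest of the multiset of positions.
    """
    if k <= 0:
        raise ValueError(f"rank k must be a positive integer, got {k}")
    positions = np.asarray(positions, dtype=float)
    if len(positions) < k:
        return math.nan
    return float(np.partition(positions, len(positions) - k)[len(positions) - k])


def front_trajectory(snapshots: SnapshotSeries, k: int) -> FrontTrajectory:
    """Rank-k front x_k(t) across the snapshot series."""
    x_k = np.array([front_position(p, k) for p in snapshots.positions])
    return FrontTrajectory(k, snapshots.times, x_k)


def fit_front_slope(
    traj: FrontTrajectory, window: Tuple[float, float] = (0.0, 1800.0)
) -> SlopeEstimate:
    """OLS slope of x_k versus t over the fit window, undefined points excluded.

    The default window is the first 30 minutes, where the progression is
    approximately linear before absorption losses bend it over.
    """
    lo, hi = window
    mask = traj.defined() & (traj.times >= lo) & (traj.times <= hi)
    n = int(mask.sum())
    if n < 2:
        return SlopeEstimate(math.nan, math.nan, window, n)
    t = traj.times[mask]
    x = traj.x_k[mask]
    res = stats.linregress(t, x)
    se = float(res.stderr) if n > 2 else 0.0
    return SlopeEstimate(float(res.slope), se, window, n)


def replicate_mean(
    trajectories: Sequence[FrontTrajectory],
) -> Tuple[FrontTrajectory, np.ndarray]:
    """Mean front over replicates with per-time SEM (NaN where undefined).

    All replicates must share the snapshot time grid.  Times where fewer
    than two replicates are defined get SEM = NaN (flagged undefined).
    """
    if not trajectories:
        raise ValueError("need at least one replicate")
    times = trajectories[0].times
    ks = {tr.k for tr in trajectories}
    if len(ks) != 1:
        raise ValueError(f"replicates mix different ranks: {sorted(ks)}")
    for tr in trajectories[1:]:
        if len(tr.times) != len(times) or np.any(tr.times != times):
            raise ValueError("replicates must share the same snapshot times")
    X = np.vstack([tr.x_k for tr in trajectories])
    counts = np.sum(~np.isnan(X), axis=0)
    mean = np.full(X.shape[1], np.nan)
    sd = np.full(X.shape[1], np.nan)
    ok = counts > 0
    if ok.any():
        mean[ok] = np.nanmean(X[:, ok], axis=0)
    ok2 = counts > 1
    if ok2.any():
        sd[ok2] = np.nanstd(X[:, ok2], axis=0, ddof=1)
    sem = sd / np.sqrt(np.maximum(counts, 1))
    return FrontTrajectory(trajectories[0].k, times, mean), sem


def saturation_check(
    traj: FrontTrajectory,
    early_window: Tuple[float, float] = (0.0, 1800.0),
    late_window: Optional[Tuple[float, float]] = None,
    ratio_threshold: float = 0.2,
) -> dict:
    """Late- versus early-window slope ratio; saturated when it collapses.

    The front is called saturated when the late-window slope falls below
    ``ratio_threshold`` times the early-window slope — the stationary
    density makes the progression function, hence x_k, time-independent.
    """
    if late_window is None:
        t_end = float(traj.times[-1])
        late_window = (t_end - (early_window[1] - early_window[0]), t_end)
    early = fit_front_slope(traj, early_window)
    late = fit_front_slope(traj, late_window)
    ratio = late.slope / early.slope if early.slope else math.nan
    return {
        "saturated": bool(ratio < ratio_threshold) if not math.isnan(ratio) else False,
        "slope_ratio": ratio,
        "early": early,
        "late": late,
    }
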