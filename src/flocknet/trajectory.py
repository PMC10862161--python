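"""GPS trajectory cleaning and synchronisation.

Raw collar fixes are cleaned with three sequential spatial-outlier filters
— (1) satellite count / paddock containment, (2) a maximum-speed rule
(default 180 m per 2 min), (3) an out-and-back spike rule combining near-cap
leg speeds with a large turning angle — and then linearly interpolated onto
an exact synchronous grid (default 2-min spacing) within each daily midday
window.  Positional accuracy of a stationary unit is summarised as the
median distance of its fixes to their coordinate-wise median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "FilterReport",
    "SyncGrid",
    "filter_satellite_bounds",
    "filter_speed",
    "filter_spikes",
    "clean_trajectory",
    "interpolate_sync",
    "estimate_accuracy",
]

#: Paper-scale defaults, all overridable at call sites.
DEFAULT_MAX_DIST = 180.0          # metres per fix interval
DEFAULT_INTERVAL = timedelta(minutes=2)
DEFAULT_MIN_SATS = 3
DEFAULT_SPIKE_LEG_FRACTION = 0.8
DEFAULT_MIN_TURN_DEG = 160.0
DEFAULT_MAX_GAP = timedelta(minutes=10)


@dataclass
class Trajectory:
    """Time-ordered fixes of one individual.

    ``fixes`` holds columns ``time`` (datetime), ``x``, ``y`` (projected
    metres) and optionally ``nsat``.  Timestamps must be strictly
    increasing.
    """

    individual_id: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        t = pd.to_datetime(self.fixes["time"])
        if len(t) > 1 and not t.is_monotonic_increasing:
            raise ValueError(
                f"{self.individual_id}: timestamps must be non-decreasing"
            )
        if t.duplicated().any():
            raise ValueError(f"{self.individual_id}: duplicate timestamps")
        self.fixes = self.fixes.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class FilterReport:
    """Book-keeping for one filter pass over one trajectory."""

    n_input: int
    n_removed_satellite_or_bounds: int = 0
    n_removed_speed: int = 0
    n_removed_spike: int = 0
    removed_indices: list[int] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_satellite_or_bounds
            + self.n_removed_speed
            + self.n_removed_spike
        )

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class SyncGrid:
    """Synchronous positions of all individuals on a common time grid.

    ``positions`` has shape (n_individuals, n_instants, 2) with NaN where
    an individual has no interpolated position; ``present`` is the matching
    availability mask.
    """

    ids: list[str]
    instants: pd.DatetimeIndex
    positions: np.ndarray
    present: np.ndarray
    interval: timedelta

    def __post_init__(self) -> None:
        n_ind, n_inst, two = self.positions.shape
        if two != 2 or n_ind != len(self.ids) or n_inst != len(self.instants):
            raise ValueError("positions shape inconsistent with ids/instants")
        if self.present.shape != (n_ind, n_inst):
            raise ValueError("present mask shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: id, instant, x, y, present."""
        rows = []
        for k, ind in enumerate(self.ids):
            rows.append(
                pd.DataFrame(
                    {
                        "id": ind,
                        "instant": self.instants,
                        "x": self.positions[k, :, 0],
                        "y": self.positions[k, :, 1],
                        "present": self.present[k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _subset(traj: Trajectory, keep: np.ndarray) -> Trajectory:
    return Trajectory(traj.individual_id, traj.fixes.loc[keep].reset_index(drop=True))


def filter_satellite_bounds(
    traj: Trajectory,
    paddock: tuple[float, float, float, float],
    min_sats: int = DEFAULT_MIN_SATS,
    buffer: float = 0.0,
) -> tuple[Trajectory, FilterReport]:
    """Drop fixes with too few satellites or clearly outside the paddock.

    ``paddock`` is (xmin, ymin, xmax, ymax) in metres; ``buffer`` widens it
    on all sides before the containment test.  Fixes without a satellite
    count pass the satellite test.
    """
    xmin, ymin, xmax, ymax = paddock
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate paddock rectangle")
    report = FilterReport(n_input=len(traj))
    if len(traj) == 0:
        return traj, report

    f = traj.fixes
    x = f["x"].to_numpy(float)
    y = f["y"].to_numpy(float)
    inside = (
        (x >= xmin - buffer)
        & (x <= xmax + buffer)
        & (y >= ymin - buffer)
        & (y <= ymax + buffer)
    )
    if "nsat" in f.columns:
        nsat = f["nsat"].to_numpy()
        enough = ~(pd.notna(nsat) & (np.nan_to_num(nsat, nan=99) < min_sats))
    else:
        enough = np.ones(len(f), bool)
    keep = inside & enough
    report.n_removed_satellite_or_bounds = int((~keep).sum())
    report.removed_indices = list(np.flatnonzero(~keep))
    return _subset(traj, keep), report


def filter_speed(
    traj: Trajectory,
    max_dist_per_interval: float = DEFAULT_MAX_DIST,
    interval: timedelta = DEFAULT_INTERVAL,
) -> tuple[Trajectory, FilterReport]:
    """Drop fixes that would require impossibly fast movement.

    Forward pass anchored at the last retained fix: fix *i* is removed when
    its distance from the last retained fix exceeds the cap scaled by the
    actual elapsed time (cap × Δt / interval), so a single teleport does not
    cascade into removing the subsequent genuine fixes.
    """
    if max_dist_per_interval <= 0:
        raise ValueError("max_dist_per_interval must be positive")
    report = FilterReport(n_input=len(traj))
    if len(traj) < 2:
        return traj, report

    f = traj.fixes
    t = pd.to_datetime(f["time"]).astype("int64").to_numpy() / 1e9
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone timestamps")
    x = f["x"].to_numpy(float)
    y = f["y"].to_numpy(float)
    dt_ref = interval.total_seconds()

    keep = np.ones(len(f), bool)
    anchor = 0
    for i in range(1, len(f)):
        dist = float(np.hypot(x[i] - x[anchor], y[i] - y[anchor]))
        allowed = max_dist_per_interval * (t[i] - t[anchor]) / dt_ref
        if dist > allowed:
            keep[i] = False
        else:
            anchor = i
    report.n_removed_speed = int((~keep).sum())
    report.removed_indices = list(np.flatnonzero(~keep))
    return _subset(traj, keep), report


def _turn_angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle between headings a→b and b→c, in degrees (0 = straight)."""
    h1 = b - a
    h2 = c - b
    n1 = np.hypot(*h1)
    n2 = np.hypot(*h2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(np.dot(h1, h2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def filter_spikes(
    traj: Trajectory,
    max_dist_per_interval: float = DEFAULT_MAX_DIST,
    interval: timedelta = DEFAULT_INTERVAL,
    min_turn_deg: float = DEFAULT_MIN_TURN_DEG,
    leg_fraction: float = DEFAULT_SPIKE_LEG_FRACTION,
) -> tuple[Trajectory, FilterReport]:
    """Drop out-and-back spike fixes.

    Interior fix B of a triple (A, B, C) is removed when both legs A→B and
    B→C exceed ``leg_fraction`` of the time-scaled speed cap *and* the
    heading change at B is at least ``min_turn_deg``.  Single left-to-right
    pass; after a removal, A stays the last retained fix.
    """
    if not 90.0 < min_turn_deg <= 180.0:
        raise ValueError("min_turn_deg must be in (90, 180]")
    report = FilterReport(n_input=len(traj))
    if len(traj) < 3:
        return traj, report

    f = traj.fixes
    t = pd.to_datetime(f["time"]).astype("int64").to_numpy() / 1e9
    xy = f[["x", "y"]].to_numpy(float)
    dt_ref = interval.total_seconds()

    keep = np.ones(len(f), bool)
    a = 0  # last retained index
    for b in range(1, len(f) - 1):
        c = b + 1
        leg1 = float(np.hypot(*(xy[b] - xy[a])))
        leg2 = float(np.hypot(*(xy[c] - xy[b])))
        cap1 = leg_fraction * max_dist_per_interval * (t[b] - t[a]) / dt_ref
        cap2 = leg_fraction * max_dist_per_interval * (t[c] - t[b]) / dt_ref
        if (
            leg1 > cap1
            and leg2 > cap2
            and _turn_angle_deg(xy[a], xy[b], xy[c]) >= min_turn_deg
        ):
            keep[b] = False
        else:
            a = b
    report.n_removed_spike = int((~keep).sum())
    report.removed_indices = list(np.flatnonzero(~keep))
    return _subset(traj, keep), report


def clean_trajectory(
    traj: Trajectory,
    paddock: tuple[float, float, float, float],
    min_sats: int = DEFAULT_MIN_SATS,
    buffer: float = 0.0,
    max_dist_per_interval: float = DEFAULT_MAX_DIST,
    interval: timedelta = DEFAULT_INTERVAL,
    min_turn_deg: float = DEFAULT_MIN_TURN_DEG,
) -> tuple[Trajectory, FilterReport]:
    """Apply the three filters in their fixed order and merge the reports."""
    t1, r1 = filter_satellite_bounds(traj, paddock, min_sats, buffer)
    t2, r2 = filter_speed(t1, max_dist_per_interval, interval)
    t3, r3 = filter_spikes(t2, max_dist_per_interval, interval, min_turn_deg)
    report = FilterReport(
        n_input=len(traj),
        n_removed_satellite_or_bounds=r1.n_removed_satellite_or_bounds,
        n_removed_speed=r2.n_removed_speed,
        n_removed_spike=r3.n_removed_spike,
    )
    return t3, report


def grid_instants(
    windows: Sequence[tuple[datetime, datetime]], interval: timedelta
) -> pd.DatetimeIndex:
    """Half-open grid [start, end) at ``interval`` spacing for each window."""
    out: list[pd.Timestamp] = []
    step = pd.Timedelta(interval)
    for start, end in windows:
        t = pd.Timestamp(start)
        end = pd.Timestamp(end)
        while t < end:
            out.append(t)
            t = t + step
    return pd.DatetimeIndex(out)


def interpolate_sync(
    trajs: Iterable[Trajectory],
    windows: Sequence[tuple[datetime, datetime]],
    interval: timedelta = DEFAULT_INTERVAL,
    max_gap: timedelta = DEFAULT_MAX_GAP,
) -> SyncGrid:
    """Linearly interpolate each trajectory onto the common window grid.

    A grid instant is missing for an individual when it lies outside the
    span of that individual's fixes or when the bracketing gap between
    retained fixes exceeds ``max_gap``.  Instants falling exactly on a fix
    take that fix's coordinates.
    """
    trajs = list(trajs)
    instants = grid_instants(windows, interval)
    gi = instants.astype("int64").to_numpy() / 1e9
    n_inst = len(instants)
    ids = [tr.individual_id for tr in trajs]
    positions = np.full((len(trajs), n_inst, 2), np.nan)
    present = np.zeros((len(trajs), n_inst), bool)
    max_gap_s = max_gap.total_seconds()

    for k, tr in enumerate(trajs):
        if len(tr) == 0:
            continue
        t = pd.to_datetime(tr.fixes["time"]).astype("int64").to_numpy() / 1e9
        x = tr.fixes["x"].to_numpy(float)
        y = tr.fixes["y"].to_numpy(float)
        if len(tr) == 1:
            hit = gi == t[0]
            positions[k, hit, 0] = x[0]
            positions[k, hit, 1] = y[0]
            present[k, hit] = True
            continue
        in_span = (gi >= t[0]) & (gi <= t[-1])
        # index of the right bracket for each in-span instant
        right = np.searchsorted(t, gi, side="left")
        right = np.clip(right, 1, len(t) - 1)
        left = right - 1
        gap_ok = (t[right] - t[left]) <= max_gap_s
        exact = np.isin(gi, t)
        ok = in_span & (gap_ok | exact)
        w = np.where(
            t[right] > t[left], (gi - t[left]) / (t[right] - t[left]), 0.0
        )
        px = x[left] + w * (x[right] - x[left])
        py = y[left] + w * (y[right] - y[left])
        positions[k, ok, 0] = px[ok]
        positions[k, ok, 1] = py[ok]
        present[k, ok] = True

    return SyncGrid(ids, instants, positions, present, interval)


def estimate_accuracy(static_fixes: pd.DataFrame) -> dict[str, float]:
    """Positional accuracy of a stationary unit.

    The unit's "true" location is taken as the coordinate-wise median of
    its fixes; the returned ``median``, ``q1`` and ``q3`` summarise the
    distances of each fix to that location, in metres.
    """
    if len(static_fixes) < 2:
        raise ValueError("need at least 2 fixes from a stationary unit")
    x = static_fixes["x"].to_numpy(float)
    y = static_fixes["y"].to_numpy(float)
    cx, cy = np.median(x), np.median(y)
    d = np.hypot(x - cx, y - cy)
    return {
        "median": float(np.median(d)),
        "q1": float(np.quantile(d, 0.25)),
        "q3": float(np.quantile(d, 0.75)),
    }
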