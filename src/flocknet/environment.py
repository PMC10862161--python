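"""Thermal environment and shade use.

Computes the sheep temperature-humidity index (THI) from dry-bulb
temperature and relative humidity, classifies heat-stress levels with the
Marai thresholds, defines the daily 3-h midday analysis window around solar
noon, and quantifies per-individual shade use as time spent inside mapped
tree-shade polygons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "HEAT_STRESS_THRESHOLDS",
    "HEAT_STRESS_CATEGORIES",
    "ThiValue",
    "ShadePatch",
    "compute_thi",
    "classify_heat_stress",
    "midday_window",
    "window_mean_thi",
    "daily_window_thi",
    "shade_use",
]

#: Marai et al. heat-stress thresholds for sheep (half-open bins).
HEAT_STRESS_THRESHOLDS = (22.2, 23.3, 25.6)

#: Category labels, ordered from no stress upward.
HEAT_STRESS_CATEGORIES = ("none", "moderate", "severe", "extreme_severe")


@dataclass(frozen=True)
class ThiValue:
    """A THI value together with its heat-stress category."""

    value: float
    category: str

    def __post_init__(self) -> None:
        if self.category != classify_heat_stress(self.value):
            raise ValueError(
                f"category {self.category!r} inconsistent with THI {self.value}"
            )


@dataclass(frozen=True)
class ShadePatch:
    """A georeferenced tree patch providing shade.

    Coordinates are planar metres in the paddock frame. ``height`` is the
    tree height in metres; patches below the eligibility height (default
    1 m) are considered too low to shade a standing sheep.
    """

    patch_id: str
    polygon: Polygon
    height: float | None = None

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"patch {self.patch_id}: polygon invalid or degenerate")


def compute_thi(T, RH, *, literal_bracketing: bool = False):
    """Sheep temperature-humidity index of Marai et al.

    THI = T − (0.31 − 0.31·RH/100) · (T − 14.4), with T the dry-bulb
    temperature in °C and RH the relative humidity in percent.  At RH = 100
    the humidity correction vanishes and THI = T; below T = 14.4 °C the
    correction changes sign and the index is not meaningful for heat stress.

    Parameters
    ----------
    T, RH
        Scalars or arrays, broadcast together.
    literal_bracketing
        Use the alternative grouping T − 0.31 + 0.31·(RH/100)·(T − 14.4)
        (sensitivity check only; not the standard index).

    Returns
    -------
    float or ndarray of the same shape as the broadcast inputs.
    """
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(RH))):
        raise ValueError("non-finite temperature or humidity")
    if np.any((RH < 0) | (RH > 100)):
        raise ValueError("relative humidity outside [0, 100]")
    if literal_bracketing:
        out = T - 0.31 + 0.31 * (RH / 100.0) * (T - 14.4)
    else:
        out = T - (0.31 - 0.31 * RH / 100.0) * (T - 14.4)
    return float(out) if out.ndim == 0 else out


def classify_heat_stress(thi: float) -> str:
    """Marai heat-stress category for one THI value.

    Bins are half-open: none < 22.2 ≤ moderate < 23.3 ≤ severe < 25.6 ≤
    extreme_severe.
    """
    if not math.isfinite(thi):
        raise ValueError("non-finite THI")
    idx = int(np.searchsorted(HEAT_STRESS_THRESHOLDS, thi, side="right"))
    return HEAT_STRESS_CATEGORIES[idx]


def thi_value(T: float, RH: float) -> ThiValue:
    """Convenience: THI plus category from one weather observation."""
    v = float(compute_thi(T, RH))
    return ThiValue(v, classify_heat_stress(v))


def midday_window(
    day: date,
    longitude: float | None = None,
    half_width: timedelta = timedelta(hours=1.5),
    *,
    centre: datetime | None = None,
) -> tuple[datetime, datetime]:
    """Half-open midday window [start, end) centred on local solar noon.

    Solar noon is approximated by mean solar time: UTC noon minus
    longitude/15 hours (positive east).  The equation-of-time correction
    (≤ ±16 min) is ignored, which is immaterial against a 3-h window; pass
    ``centre`` to override with an explicit clock time.
    """
    if half_width <= timedelta(0):
        raise ValueError("half_width must be positive")
    if centre is None:
        if longitude is None or not -180.0 <= longitude <= 180.0:
            raise ValueError("longitude must be in [-180, 180] unless centre is given")
        noon_utc = datetime(day.year, day.month, day.day, 12, tzinfo=timezone.utc)
        centre = noon_utc - timedelta(hours=longitude / 15.0)
    return centre - half_width, centre + half_width


def window_mean_thi(
    weather: pd.DataFrame, window: tuple[datetime, datetime]
) -> ThiValue:
    """Mean THI of the weather records falling inside a half-open window.

    ``weather`` needs columns ``timestamp`` (datetime-like), ``temp_c`` and
    ``rh_pct``.  The heat-stress category is assigned from the mean.
    """
    start, end = window
    ts = pd.to_datetime(weather["timestamp"])
    mask = (ts >= start) & (ts < end)
    if not mask.any():
        raise ValueError(f"no weather records inside window starting {start}")
    sub = weather.loc[mask]
    thi = compute_thi(sub["temp_c"].to_numpy(), sub["rh_pct"].to_numpy())
    mean = float(np.mean(thi))
    return ThiValue(mean, classify_heat_stress(mean))


def daily_window_thi(
    weather: pd.DataFrame, windows: Sequence[tuple[datetime, datetime]]
) -> pd.DataFrame:
    """Per-window mean THI for a sequence of daily midday windows.

    Returns a frame with columns day (date of window start), thi, category.
    """
    rows = []
    for start, end in windows:
        tv = window_mean_thi(weather, (start, end))
        rows.append({"day": pd.Timestamp(start).date(), "thi": tv.value,
                     "category": tv.category})
    return pd.DataFrame(rows)


def _eligible_union(patches: Iterable[ShadePatch], min_height: float):
    polys = [
        p.polygon
        for p in patches
        if p.height is None or p.height >= min_height
    ]
    if not polys:
        return None
    return shapely.union_all(polys)


def shade_use(
    grid,
    patches: Iterable[ShadePatch],
    windows: Sequence[tuple[datetime, datetime]],
    min_height: float = 1.0,
) -> pd.DataFrame:
    """Per-individual, per-day shade use from the synchronous grid.

    Counts the present grid positions of each individual that fall inside
    the union of shade polygons at least ``min_height`` tall (boundary
    points count as shaded — a sheep at the drip line is under the canopy)
    and converts the count to minutes at 2 min per fix.  Missing grid
    instants contribute nothing.

    Returns a frame with columns id, day, fixes_in_shade, minutes covering
    every (individual, window) combination.
    """
    union = _eligible_union(patches, min_height)
    instants = pd.DatetimeIndex(grid.instants)
    minutes_per_fix = grid.interval.total_seconds() / 60.0

    rows = []
    for start, end in windows:
        day = pd.Timestamp(start).date()
        in_win = (instants >= start) & (instants < end)
        for k, ind in enumerate(grid.ids):
            present = grid.present[k] & in_win
            if union is None or not present.any():
                count = 0
            else:
                xy = grid.positions[k, present]
                count = int(
                    np.count_nonzero(
                        shapely.intersects_xy(union, xy[:, 0], xy[:, 1])
                    )
                )
            rows.append(
                {
                    "id": ind,
                    "day": day,
                    "fixes_in_shade": count,
                    "minutes": minutes_per_fix * count,
                }
            )
    return pd.DataFrame(rows)
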