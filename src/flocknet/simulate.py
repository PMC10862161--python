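"""Seedable synthetic flock generator.

Emulates the study design the downstream pipeline expects — a flock of
GPS-collared sheep in a rectangular paddock dotted with tree-shade patches,
tracked at a fixed interval through a daily midday window, under a weather
series whose midday THI spans the Marai heat-stress categories — without
any field data.

The movement rule is a discrete-time biased correlated random walk, not a
behavioural model: its only contract is statistical.  Per step each
individual combines (i) an AR(1) heading carrying the stochastic
exploration, (ii) attraction toward the flock centroid (weight
``social_attraction``; also the mean-reversion that keeps the flock
contained), and (iii) attraction toward the nearest eligible shade patch
whose weight grows with daily THI × individual shade propensity ×
``shade_thi_slope``; once under a patch the same weight damps movement, so
hot days hold shade-seeking sheep in place.  With both couplings at zero
the rule degenerates to independent correlated random walks whose marginal
position is uniform over the paddock.

:func:`inject_artifacts` adds the defect classes the cleaning filters
target (low-satellite fixes, teleports, out-and-back spikes, dropped fixes,
per-collar clock offsets) with ground-truth labels retained.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from .environment import ShadePatch, compute_thi
from shapely.geometry import Polygon

__all__ = [
    "SimConfig",
    "ArtifactRates",
    "SyntheticDataset",
    "simulate_weather",
    "simulate_patches",
    "simulate_flock",
    "simulate_dataset",
    "inject_artifacts",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one synthetic deployment.

    Defaults mirror the field campaign the pipeline is built for: 48 ewes,
    82 consecutive days, 2-min synchronous fixes across a 3-h midday
    window, a 6 × 1 km paddock with 106 tree patches, and midday THI
    between 20.72 and 34.29.
    """

    n_individuals: int = 48
    n_days: int = 82
    fix_interval_min: float = 2.0
    window_length_h: float = 3.0
    paddock: tuple[float, float] = (6000.0, 1000.0)   # metres (x, y)
    n_shade_patches: int = 106
    shade_propensity: float | Sequence[float] | None = None  # None -> Beta(2,2)
    social_attraction: float = 0.08
    shade_thi_slope: float = 0.08      # per THI unit above thi_ref
    thi_range: tuple[float, float] = (20.72, 34.29)
    noise_sd: float = 12.0             # metres per step
    seed: int = 0

    # secondary knobs (movement and habitat texture)
    persistence: float = 0.4           # AR(1) heading coefficient
    thi_ref: float = 22.2              # no-stress threshold anchors coupling
    shade_speed: float = 60.0          # max metres per step toward shade
    step_cap: float = 160.0            # hard cap, below the 180 m filter cap
    window_start_hour: float = 11.5    # UTC hours; fixed-clock midday window
    start_date: date = date(2018, 1, 1)
    rh_range: tuple[float, float] = (25.0, 65.0)
    patch_area_median: float = 1500.0  # m^2, log-normal spread
    patch_area_sigma: float = 0.6
    tree_height_median: float = 2.0    # metres, log-normal
    tree_height_sigma: float = 0.45
    nsat_default: int = 8

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_days, self.n_shade_patches) <= 0:
            raise ValueError("counts must be positive")
        if self.fix_interval_min <= 0 or self.window_length_h <= 0:
            raise ValueError("interval and window length must be positive")
        if self.paddock[0] <= 0 or self.paddock[1] <= 0:
            raise ValueError("paddock must have positive area")
        if self.thi_range[0] > self.thi_range[1]:
            raise ValueError("thi_range must be (min, max) with min <= max")
        if self.social_attraction < 0:
            raise ValueError("social_attraction must be >= 0")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")

    @property
    def steps_per_window(self) -> int:
        return int(round(self.window_length_h * 60 / self.fix_interval_min))

    def windows(self) -> list[tuple[datetime, datetime]]:
        """Daily half-open midday windows at the fixed clock centre."""
        out = []
        for d in range(self.n_days):
            day = self.start_date + timedelta(days=d)
            start = datetime(day.year, day.month, day.day,
                             tzinfo=timezone.utc) + timedelta(
                hours=self.window_start_hour
            )
            out.append((start, start + timedelta(hours=self.window_length_h)))
        return out

    def propensities(self) -> np.ndarray:
        """Per-individual shade propensities in [0, 1].

        Drawn Beta(2, 2) when unspecified — individuals vary but extremes
        are rare, matching repeatable-but-heterogeneous shade use; a scalar
        or per-individual sequence overrides.
        """
        if self.shade_propensity is None:
            rng = np.random.default_rng([self.seed, 11])
            return rng.beta(2.0, 2.0, size=self.n_individuals)
        p = np.asarray(self.shade_propensity, float)
        if p.ndim == 0:
            p = np.full(self.n_individuals, float(p))
        if p.shape != (self.n_individuals,) or np.any((p < 0) | (p > 1)):
            raise ValueError("shade_propensity must be scalars in [0, 1]")
        return p


@dataclass(frozen=True)
class ArtifactRates:
    """Rates of injected GPS defects (all per eligible fix, in [0, 1])."""

    low_sat: float = 0.0
    teleport: float = 0.0
    spike: float = 0.0
    deletion: float = 0.0
    clock_jitter_s: float = 0.0   # per-collar offset drawn U(-j, +j)

    def __post_init__(self) -> None:
        for name in ("low_sat", "teleport", "spike", "deletion"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} rate {r} outside [0, 1]")
        if not 0.0 <= self.clock_jitter_s <= 30.0:
            raise ValueError("clock_jitter_s must be within [0, 30] seconds")


@dataclass
class SyntheticDataset:
    """Fixes, habitat, weather and the generating truth of one simulation."""

    fixes: pd.DataFrame                 # id, time, x, y, nsat, artifact
    patches: list[ShadePatch]
    weather: pd.DataFrame               # timestamp, temp_c, rh_pct
    windows: list[tuple[datetime, datetime]]
    config: SimConfig
    truth: dict

    def truth_json(self) -> str:
        return json.dumps(self.truth, sort_keys=True)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------


def _daily_thi_targets(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.thi_range
    n = config.n_days
    if hi == lo:
        return np.full(n, float(lo))
    strata = (np.arange(n) + rng.uniform(size=n)) / n
    return rng.permutation(lo + (hi - lo) * strata)


def _temp_for_thi(thi: np.ndarray, rh: np.ndarray) -> np.ndarray:
    """Invert the THI formula for T at given RH (valid for THI >= 14.4)."""
    c = 0.31 * (1.0 - rh / 100.0)
    return (thi - 14.4 * c) / (1.0 - c)


def simulate_weather(config: SimConfig) -> pd.DataFrame:
    """Hourly dry-bulb temperature and relative humidity records.

    Daily midday-window THI targets are stratified over ``thi_range`` (so
    the series fills the range, hitting every Marai category the range
    covers) and shuffled into a day order.  Within each day's midday
    window the temperature is set from the target THI and the day's
    humidity, so the window-mean THI reproduces the target exactly;
    off-window hours follow a plain diurnal curve.
    """
    if config.thi_range[0] < 14.4:
        raise ValueError(
            "thi_range below 14.4 is outside the index's heat-stress domain "
            "(the humidity correction inverts)"
        )
    rng = np.random.default_rng([config.seed, 1])
    targets = _daily_thi_targets(config, rng)
    rh = rng.uniform(*config.rh_range, size=config.n_days)
    windows = config.windows()

    rows = []
    for d in range(config.n_days):
        day = config.start_date + timedelta(days=d)
        t_mid = float(_temp_for_thi(np.array(targets[d]), np.array(rh[d])))
        start, end = windows[d]
        # windows shorter than an hour may straddle no whole-hour record;
        # the hour containing the window centre then carries the target
        centre_hour = (start + (end - start) / 2).replace(
            minute=0, second=0, microsecond=0
        )
        for hour in range(24):
            ts = datetime(day.year, day.month, day.day, hour,
                          tzinfo=timezone.utc)
            if start <= ts < end or ts == centre_hour:
                temp = t_mid
            else:
                # diurnal sinusoid peaking near the window, 8 deg amplitude
                temp = (t_mid - 2.0) + 8.0 * (
                    np.cos((hour - 13.0) / 24.0 * 2 * np.pi) - 1.0
                ) / 2.0
            rows.append(
                {"timestamp": ts, "temp_c": float(temp),
                 "rh_pct": float(rh[d])}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# habitat
# ---------------------------------------------------------------------------


def simulate_patches(config: SimConfig) -> list[ShadePatch]:
    """Convex shade polygons with log-normal areas and tree heights.

    Patch centres are uniform over the paddock interior; each polygon has
    4–8 vertices.  Heights are log-normal around ~2 m, so a small fraction
    falls below the 1-m shading eligibility cut and exercises that filter.
    """
    rng = np.random.default_rng([config.seed, 2])
    w, h = config.paddock
    margin = 60.0
    patches = []
    for k in range(config.n_shade_patches):
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        area = rng.lognormal(np.log(config.patch_area_median),
                             config.patch_area_sigma)
        r0 = np.sqrt(area / np.pi)
        n_vert = int(rng.integers(4, 9))
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
        rad = r0 * rng.uniform(0.75, 1.25, size=n_vert)
        xs = np.clip(cx + rad * np.cos(ang), 1.0, w - 1.0)
        ys = np.clip(cy + rad * np.sin(ang), 1.0, h - 1.0)
        poly = Polygon(zip(xs, ys))
        if not poly.is_valid or poly.area <= 0:
            poly = poly.buffer(0)
        height = float(rng.lognormal(np.log(config.tree_height_median),
                                     config.tree_height_sigma))
        patches.append(ShadePatch(patch_id=f"patch_{k:03d}", polygon=poly,
                                  height=round(height, 2)))
    return patches


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------


def _reflect(x: np.ndarray, v: np.ndarray, lo: float, hi: float) -> None:
    """Reflect coordinates into [lo, hi] in place, mirroring the heading.

    Exact billiard folding: however far a step overshoots, the point lands
    where repeated boundary reflections would put it, which keeps a uniform
    position distribution uniform.
    """
    length = hi - lo
    r = np.mod(x - lo, 2.0 * length)
    descending = r > length
    x[:] = lo + np.where(descending, 2.0 * length - r, r)
    v[descending] = -v[descending]


def simulate_flock(config: SimConfig, weather: pd.DataFrame) -> SyntheticDataset:
    """Synchronous flock trajectories over all daily midday windows.

    Requires a weather table covering every simulated day (as produced by
    :func:`simulate_weather`); the midday-window mean THI of each day sets
    that day's shade-attraction weights.
    """
    windows = config.windows()
    ts = pd.to_datetime(weather["timestamp"])
    daily_thi = []
    for start, end in windows:
        mask = (ts >= start) & (ts < end)
        if not mask.any():
            raise ValueError(f"weather does not cover window starting {start}")
        sub = weather.loc[mask]
        daily_thi.append(float(np.mean(
            compute_thi(sub["temp_c"].to_numpy(), sub["rh_pct"].to_numpy())
        )))
    daily_thi = np.asarray(daily_thi)

    patches = simulate_patches(config)
    eligible = [p for p in patches if (p.height or 0.0) >= 1.0]
    if eligible:
        cent = np.array([[p.polygon.centroid.x, p.polygon.centroid.y]
                         for p in eligible])
        r_eff = np.array([np.sqrt(p.polygon.area / np.pi) for p in eligible])
    else:
        cent = np.zeros((0, 2))
        r_eff = np.zeros(0)

    prop = config.propensities()
    rng = np.random.default_rng([config.seed, 3])
    w, h = config.paddock
    n = config.n_individuals
    steps = config.steps_per_window
    null_mode = config.social_attraction == 0 and config.shade_thi_slope == 0
    ids = [f"sheep_{k:02d}" for k in range(n)]

    all_times: list[np.ndarray] = []
    all_xy: list[np.ndarray] = []
    for d, (start, _end) in enumerate(windows):
        # shade-attraction weight per individual for this day
        wshade = np.minimum(
            1.0,
            config.shade_thi_slope * prop * max(daily_thi[d] - config.thi_ref, 0.0),
        )
        if null_mode:
            x = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
        else:
            c0 = np.array([rng.uniform(150, w - 150), rng.uniform(150, h - 150)])
            x = c0 + rng.normal(0, 40, size=(n, 2))
            x[:, 0] = np.clip(x[:, 0], 0, w)
            x[:, 1] = np.clip(x[:, 1], 0, h)
        heading = np.zeros((n, 2))

        xy = np.empty((steps, n, 2))
        xy[0] = x
        for t in range(1, steps):
            heading = config.persistence * heading + rng.normal(
                0, config.noise_sd, size=(n, 2)
            )
            step = heading.copy()
            if config.social_attraction > 0:
                centroid = x.mean(axis=0)
                step += config.social_attraction * (centroid - x)
            if cent.size and np.any(wshade > 0):
                diff = cent[None, :, :] - x[:, None, :]      # (n, K, 2)
                dist = np.hypot(diff[..., 0], diff[..., 1])  # (n, K)
                nearest = np.argmin(dist, axis=1)
                dvec = diff[np.arange(n), nearest]
                dlen = dist[np.arange(n), nearest]
                gain = np.minimum(dlen, config.shade_speed) / np.maximum(dlen, 1e-9)
                step += wshade[:, None] * dvec * gain[:, None]
                # under the canopy hot shade-seekers mostly stay put
                inside = dlen <= r_eff[nearest]
                damp = np.where(inside, 1.0 - 0.9 * wshade, 1.0)
                step *= damp[:, None]
            slen = np.hypot(step[:, 0], step[:, 1])
            over = slen > config.step_cap
            if over.any():
                step[over] *= (config.step_cap / slen[over])[:, None]
            x = x + step
            _reflect(x[:, 0], heading[:, 0], 0.0, w)
            _reflect(x[:, 1], heading[:, 1], 0.0, h)
            xy[t] = x

        times = np.array(
            [start + k * timedelta(minutes=config.fix_interval_min)
             for k in range(steps)]
        )
        all_times.append(times)
        all_xy.append(xy)

    frames = []
    for d in range(len(windows)):
        xy = all_xy[d]
        for k, ind in enumerate(ids):
            frames.append(
                pd.DataFrame(
                    {
                        "id": ind,
                        "time": all_times[d],
                        "x": xy[:, k, 0],
                        "y": xy[:, k, 1],
                        "nsat": config.nsat_default,
                    }
                )
            )
    fixes = pd.concat(frames, ignore_index=True)
    fixes["artifact"] = "none"
    fixes = fixes.sort_values(["id", "time"], kind="stable").reset_index(drop=True)

    truth = {
        "seed": config.seed,
        "shade_propensity": {i: float(p) for i, p in zip(ids, prop)},
        "social_attraction": config.social_attraction,
        "shade_thi_slope": config.shade_thi_slope,
        "daily_thi": [float(v) for v in daily_thi],
        "artifacts": {},
    }
    return SyntheticDataset(
        fixes=fixes,
        patches=patches,
        weather=weather,
        windows=windows,
        config=config,
        truth=truth,
    )


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Weather plus flock in one call."""
    return simulate_flock(config, simulate_weather(config))


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


def inject_artifacts(
    dataset: SyntheticDataset,
    rates: ArtifactRates,
    seed: int | None = None,
) -> SyntheticDataset:
    """Corrupt a clean dataset with labelled GPS defects.

    Low-satellite fixes get nsat < 3 and a random offset; teleports are
    displaced beyond the speed cap; spikes become out-and-back excursions
    that pass the speed filter but trip the turning-angle rule; fixes are
    deleted at random; and each collar's clock is offset by up to the
    configured jitter.  The returned copy carries an ``artifact`` label per
    fix and the injected indices in ``truth["artifacts"]``.
    """
    rng = np.random.default_rng(
        [dataset.config.seed, 4] if seed is None else seed
    )
    fixes = dataset.fixes.copy().reset_index(drop=True)
    w, h = dataset.config.paddock
    cap = 180.0
    n = len(fixes)
    label = fixes["artifact"].to_numpy(object).copy()

    # positions of each individual's run for interior-fix bookkeeping
    first_last = set()
    for _ind, grp in fixes.groupby("id").groups.items():
        idx = np.asarray(grp)
        first_last.add(int(idx[0]))
        first_last.add(int(idx[-1]))

    def pick(rate: float, eligible: np.ndarray) -> np.ndarray:
        if rate <= 0 or eligible.size == 0:
            return np.array([], int)
        return eligible[rng.uniform(size=eligible.size) < rate]

    x = fixes["x"].to_numpy(float).copy()
    y = fixes["y"].to_numpy(float).copy()
    nsat = fixes["nsat"].to_numpy(float).copy()

    clean = np.flatnonzero(label == "none")
    sat_idx = pick(rates.low_sat, clean)
    if sat_idx.size:
        nsat[sat_idx] = rng.integers(0, 3, size=sat_idx.size)
        x[sat_idx] = np.clip(x[sat_idx] + rng.normal(0, 120, sat_idx.size), 0, w)
        y[sat_idx] = np.clip(y[sat_idx] + rng.normal(0, 120, sat_idx.size), 0, h)
        label[sat_idx] = "low_sat"

    clean = np.flatnonzero(label == "none")
    tele_idx = pick(rates.teleport, clean)
    if tele_idx.size:
        ang = rng.uniform(0, 2 * np.pi, tele_idx.size)
        r = rng.uniform(1.5 * cap, 3.0 * cap, tele_idx.size)
        x[tele_idx] = np.clip(x[tele_idx] + r * np.cos(ang), 0, w)
        y[tele_idx] = np.clip(y[tele_idx] + r * np.sin(ang), 0, h)
        label[tele_idx] = "teleport"

    # spikes need clean interior fixes with clean 2-min neighbours
    interval_s = dataset.config.fix_interval_min * 60.0
    t_s = pd.to_datetime(fixes["time"]).astype("int64").to_numpy() / 1e9
    same_id = fixes["id"].to_numpy()
    eligible = []
    for i in np.flatnonzero(label == "none"):
        if i in first_last or i - 1 < 0 or i + 1 >= n:
            continue
        if same_id[i - 1] != same_id[i] or same_id[i + 1] != same_id[i]:
            continue
        if label[i - 1] != "none" or label[i + 1] != "none":
            continue
        if (t_s[i] - t_s[i - 1]) != interval_s or (t_s[i + 1] - t_s[i]) != interval_s:
            continue
        eligible.append(i)
    spike_idx = pick(rates.spike, np.asarray(eligible, int))
    placed = []
    for i in spike_idx:
        ax, ay = x[i - 1], y[i - 1]
        cx, cy = x[i + 1], y[i + 1]
        ex, ey = (cx - ax) / 2.0, (cy - ay) / 2.0
        if np.hypot(2 * ex, 2 * ey) > 100.0:
            continue
        ux, uy = -ey, ex
        norm = np.hypot(ux, uy)
        if norm < 1e-9:
            ux, uy = 0.0, 1.0
            norm = 1.0
        sgn = 1.0 if rng.uniform() < 0.5 else -1.0
        r = 0.9 * cap * rng.uniform(0.98, 1.02)
        x[i] = ax + ex + sgn * r * ux / norm
        y[i] = ay + ey + sgn * r * uy / norm
        label[i] = "spike"
        placed.append(int(i))

    fixes["x"] = x
    fixes["y"] = y
    fixes["nsat"] = nsat.astype(int)
    fixes["artifact"] = label

    keep = np.ones(n, bool)
    del_idx = pick(rates.deletion, np.arange(n))
    keep[del_idx] = False
    deleted = fixes.loc[~keep, ["id", "time"]]
    fixes = fixes.loc[keep].reset_index(drop=True)

    if rates.clock_jitter_s > 0:
        offsets = {
            ind: rng.uniform(-rates.clock_jitter_s, rates.clock_jitter_s)
            for ind in sorted(fixes["id"].unique())
        }
        fixes["time"] = fixes["time"] + pd.to_timedelta(
            fixes["id"].map(offsets), unit="s"
        )

    truth = dict(dataset.truth)
    truth["artifacts"] = {
        "low_sat": [int(i) for i in sat_idx],
        "teleport": [int(i) for i in tele_idx],
        "spike": placed,
        "deleted": deleted.assign(
            time=deleted["time"].astype(str)
        ).to_dict("records"),
        "clock_jitter_s": rates.clock_jitter_s,
    }
    return SyntheticDataset(
        fixes=fixes,
        patches=dataset.patches,
        weather=dataset.weather,
        windows=dataset.windows,
        config=dataset.config,
        truth=truth,
    )
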