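"""End-to-end pipeline: simulate → clean → environment → network → infer.

A single YAML-serialisable :class:`RunConfig` drives all stages; every
study constant (association threshold inputs, speed cap, satellite
minimum, shade height cut, permutation count, Marai thresholds via the
environment module) is a named key rather than a hard-coded literal.  Runs
are deterministic given the config, and the manifest records a checksum
per artefact so re-runs can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .environment import daily_window_thi, shade_use
from .inference import run_full_inference
from .simulate import ArtifactRates, SimConfig, inject_artifacts, simulate_dataset
from .socialnet import association_threshold, gbi_by_window, sri_network
from .trajectory import Trajectory, clean_trajectory, interpolate_sync

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("flocknet")


@dataclass
class RunConfig:
    """All stage parameters of one reproducible run."""

    out_dir: str = "flocknet_run"
    sim: SimConfig = field(default_factory=SimConfig)
    artifacts: ArtifactRates = field(default_factory=ArtifactRates)
    # cleaning
    min_sats: int = 3
    paddock_buffer_m: float = 10.0
    max_dist_per_interval_m: float = 180.0
    min_turn_deg: float = 160.0
    max_gap_min: float = 10.0
    # association
    body_length_m: float = 1.0
    unit_accuracy_m: float = 2.0   # per-unit accuracy, rounded up
    # shade
    min_tree_height_m: float = 1.0
    # inference
    n_perm: int = 1000
    swaps_per_step: int = 10
    burn_in: int = 1000
    seed: int = 0
    make_figures: bool = True

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"]["start_date"] = str(self.sim.start_date)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("sim", {})
        if "start_date" in sim:
            from datetime import date

            sim["start_date"] = date.fromisoformat(sim["start_date"])
        if "shade_propensity" in sim and isinstance(sim["shade_propensity"], list):
            sim["shade_propensity"] = tuple(sim["shade_propensity"])
        if "paddock" in sim:
            sim["paddock"] = tuple(sim["paddock"])
        if "thi_range" in sim:
            sim["thi_range"] = tuple(sim["thi_range"])
        if "rh_range" in sim:
            sim["rh_range"] = tuple(sim["rh_range"])
        art = d.pop("artifacts", {})
        return cls(sim=SimConfig(**sim), artifacts=ArtifactRates(**art), **d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["sim"]["start_date"] = str(self.sim.start_date)
        d.pop("out_dir")  # where outputs land does not change what they are
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=float).encode()
        ).hexdigest()[:12]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the artefact manifest.

    Stages run in a fixed order; any failure propagates with the stage
    name.  Outputs land under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stamp = config.config_hash()
    timings: dict[str, float] = {}

    def record(path: Path) -> None:
        manifest[str(path.relative_to(out))] = _checksum(path)

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    try:
        name = stage("simulate")
        dataset = simulate_dataset(config.sim)
        if any(
            getattr(config.artifacts, f) > 0
            for f in ("low_sat", "teleport", "spike", "deletion", "clock_jitter_s")
        ):
            dataset = inject_artifacts(dataset, config.artifacts)
        fio.write_fixes_csv(dataset.fixes, out / "fixes.csv")
        fio.write_weather_csv(dataset.weather, out / "weather.csv")
        fio.write_patches_geojson(dataset.patches, out / "patches.geojson")
        fio.write_truth_json(dataset.truth, out / "truth.json")
        for p in ("fixes.csv", "weather.csv", "patches.geojson", "truth.json"):
            record(out / p)
        timings[name] = time.perf_counter() - timings[name]

        name = stage("clean")
        w, h = config.sim.paddock
        paddock = (0.0, 0.0, w, h)
        from datetime import timedelta

        interval = timedelta(minutes=config.sim.fix_interval_min)
        cleaned = []
        n_removed = 0
        for ind, grp in dataset.fixes.groupby("id", sort=True):
            traj = Trajectory(str(ind), grp[["time", "x", "y", "nsat"]])
            tclean, rep = clean_trajectory(
                traj,
                paddock,
                min_sats=config.min_sats,
                buffer=config.paddock_buffer_m,
                max_dist_per_interval=config.max_dist_per_interval_m,
                interval=interval,
                min_turn_deg=config.min_turn_deg,
            )
            cleaned.append(tclean)
            n_removed += rep.n_removed
        log.info("clean: removed %d fixes", n_removed)
        grid = interpolate_sync(
            cleaned,
            dataset.windows,
            interval=interval,
            max_gap=timedelta(minutes=config.max_gap_min),
        )
        grid.to_frame().to_csv(out / "grid.csv", index=False)
        record(out / "grid.csv")
        timings[name] = time.perf_counter() - timings[name]

        name = stage("environment")
        thi_daily = daily_window_thi(dataset.weather, dataset.windows)
        thi_daily.to_csv(out / "thi_daily.csv", index=False)
        shade = shade_use(
            grid, dataset.patches, dataset.windows,
            min_height=config.min_tree_height_m,
        )
        shade.to_csv(out / "shade_use.csv", index=False)
        record(out / "thi_daily.csv")
        record(out / "shade_use.csv")
        timings[name] = time.perf_counter() - timings[name]

        name = stage("network")
        threshold = association_threshold(
            config.body_length_m, config.unit_accuracy_m
        )
        gbis = gbi_by_window(grid, threshold, dataset.windows)
        edges = []
        for k, gbi in enumerate(gbis):
            net = sri_network(gbi)
            iu = np.triu_indices(net.n, 1)
            for i, j in zip(*iu):
                if net.weights[i, j] > 0:
                    edges.append(
                        {
                            "day_index": k,
                            "i": net.ids[i],
                            "j": net.ids[j],
                            "sri": net.weights[i, j],
                            "together": int(net.together[i, j]),
                            "both_recorded": int(net.both_recorded[i, j]),
                        }
                    )
        pd.DataFrame(edges).to_csv(out / "edges.csv", index=False)
        record(out / "edges.csv")
        timings[name] = time.perf_counter() - timings[name]

        name = stage("infer")
        results = run_full_inference(
            gbis,
            thi_daily["thi"].to_numpy(),
            shade,
            n_perm=config.n_perm,
            seed=config.seed,
            swaps_per_step=config.swaps_per_step,
            burn_in=config.burn_in,
            progress=lambda s: log.info("infer: %s", s),
        )
        results.whole_network_table.to_csv(out / "table_whole_network.csv",
                                           index=False)
        results.node_table.to_csv(out / "table_node_level.csv", index=False)
        results.daily_metrics.to_csv(out / "daily_metrics.csv", index=False)
        nulls = {
            key: pr.null_sample.tolist()
            for key, pr in results.permutations.items()
        }
        (out / "null_distributions.json").write_text(json.dumps(nulls))
        for p in (
            "table_whole_network.csv",
            "table_node_level.csv",
            "daily_metrics.csv",
            "null_distributions.json",
        ):
            record(out / p)
        timings[name] = time.perf_counter() - timings[name]

        if config.make_figures:
            name = stage("figures")
            from .plotting import plot_metric_curves, plot_network_snapshots

            snap = plot_network_snapshots(
                gbis, thi_daily, shade, grid, out / "fig_networks.png"
            )
            curves = plot_metric_curves(results, out / "fig_node_metrics.png")
            for p in [snap, curves]:
                if p is not None:
                    record(Path(p))
            timings[name] = time.perf_counter() - timings[name]
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed in stage {name!r}: {exc}") from exc

    meta = {
        "config_hash": stamp,
        "package_version": __import__("flocknet").__version__,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "manifest": manifest,
    }
    (out / "manifest.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    config.to_yaml(out / "run_config.yaml")
    return meta
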