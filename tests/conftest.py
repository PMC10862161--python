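"""Shared fixtures: small synthetic deployments and grid builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flocknet import SimConfig, Trajectory, interpolate_sync, simulate_dataset


def dataset_to_grid(dataset, **interp_kwargs):
    """Raw fixes of a synthetic dataset onto the synchronous grid."""
    trajs = [
        Trajectory(str(ind), grp[["time", "x", "y", "nsat"]])
        for ind, grp in dataset.fixes.groupby("id", sort=True)
    ]
    return interpolate_sync(trajs, dataset.windows, **interp_kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    """6 sheep, 5 days, cohesive flock with THI-coupled shade attraction."""
    cfg = SimConfig(n_individuals=6, n_days=5, n_shade_patches=20, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_grid(small_dataset):
    return dataset_to_grid(small_dataset)


def make_grid(positions, ids=None, interval_min=2.0, present=None):
    """Hand-built SyncGrid from a (n_ind, n_inst, 2) position array."""
    from datetime import timedelta

    from flocknet import SyncGrid

    positions = np.asarray(positions, float)
    n_ind, n_inst, _ = positions.shape
    if ids is None:
        ids = [f"s{k}" for k in range(n_ind)]
    instants = pd.date_range(
        "2018-01-01T11:30Z", periods=n_inst, freq=f"{int(interval_min * 60)}s"
    )
    if present is None:
        present = np.isfinite(positions[..., 0])
    return SyncGrid(
        ids=list(ids),
        instants=instants,
        positions=positions,
        present=np.asarray(present, bool),
        interval=timedelta(minutes=interval_min),
    )
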