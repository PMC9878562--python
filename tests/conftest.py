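"""Shared fixtures: small hand-built tables and cached full-scale simulations."""

from __future__ import annotations

import functools

import numpy as np
import pandas as pd
import pytest

import chemorelay as cr


def make_table(tracks: dict[str, tuple[str, np.ndarray]], dt: float = 60.0,
               polarity: dict[str, np.ndarray] | None = None) -> cr.TrackTable:
    """Build a TrackTable from {cell_id: (group, (n, 3) positions)}."""
    rows = []
    for cid, (group, pos) in tracks.items():
        pos = np.asarray(pos, dtype=float)
        df = pd.DataFrame({
            "cell_id": cid, "group": group,
            "frame": np.arange(len(pos)), "t": np.arange(len(pos)) * dt,
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        })
        if polarity and cid in polarity:
            p = np.asarray(polarity[cid], dtype=float)
            df[["pol_x", "pol_y", "pol_z"]] = p
        rows.append(df)
    return cr.TrackTable(pd.concat(rows, ignore_index=True))


def straight_track(n: int, speed_um_min: float, dt: float = 60.0,
                   direction=(1.0, 0.0, 0.0), origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    step = speed_um_min * dt / 60.0
    return np.asarray(origin) + step * np.arange(n)[:, None] * d


@functools.lru_cache(maxsize=None)
def sim_cached(preset_name: str, seed: int):
    """Full-scale simulation of a preset, shared across the whole session."""
    return cr.simulate(cr.preset(preset_name, seed=seed))


@functools.lru_cache(maxsize=None)
def metrics_cached(preset_name: str, seed: int) -> pd.DataFrame:
    table, _ = sim_cached(preset_name, seed)
    tcfg = cr.TrackletConfig()
    return cr.metrics_table(cr.decompose(table, tcfg), tcfg)


@pytest.fixture(scope="session")
def mixed_run():
    """Reference mixed 1:1 simulation (seed 1) with metrics and gates."""
    table, truth = sim_cached("mixed_1to1", 1)
    metrics = metrics_cached("mixed_1to1", 1)
    gated = cr.classify_table(metrics, cr.GateConfig(seed=1))
    return table, truth, metrics, gated


@pytest.fixture(scope="session")
def ko_alone_run():
    table, truth = sim_cached("ko_alone", 1)
    return table, truth, metrics_cached("ko_alone", 1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
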