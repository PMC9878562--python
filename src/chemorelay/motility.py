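"""Tracklet decomposition and instantaneous motility measures.

Tracks are cut into fixed-length fragments (tracklets) and each fragment is
summarized by five scalar descriptors:

* displacement ``D`` — straight-line distance start to end (µm);
* path length ``L`` — sum of step lengths (µm), always >= D;
* velocity ``v`` — L divided by elapsed time (µm/min);
* arrest coefficient ``A`` in [0, 1] — fraction of steps whose instantaneous
  speed falls below an arrest threshold, i.e. the proportion of time the
  cell does not move;
* directionality ``Gamma`` in [0, 1] — straightness D/L, high for polarized
  cells migrating along straight trajectories.  For near-stationary
  fragments (L below a small floor) D/L is numerically meaningless; if
  per-frame polarity vectors are available the coherence of those vectors
  (norm of their mean) is used instead, otherwise Gamma = 0.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .track_io import TrackTable, DT_RTOL

logger = logging.getLogger("chemorelay")

__all__ = [
    "TrackletConfig",
    "Tracklet",
    "MotilityMetrics",
    "decompose",
    "summarize_track",
    "arrest_coefficient",
    "directionality",
    "metrics_table",
]


@dataclasses.dataclass(frozen=True)
class TrackletConfig:
    """Parameters of the tracklet decomposition and metric definitions.

    Attributes
    ----------
    window
        Frames per tracklet (W >= 2).  Default 10 frames (3.3 min at 20 s
        sampling), a timescale on which cell turning is visible.
    stride
        Frames between tracklet starts; ``None`` means ``window`` (disjoint
        tracklets, which keeps per-group samples free of autocorrelated
        duplicates).
    v_arrest
        Arrest threshold in µm/min; a step slower than this counts as
        arrested.  Default 2 µm/min, below jitter-corrected lymphocyte
        speeds.
    eps_path
        Path-length floor (µm) under which D/L is replaced by the polarity
        fallback (or 0).
    polarity_fallback
        Whether to use polarity coherence for near-stationary tracklets when
        polarity vectors are present.
    """

    window: int = 10
    stride: int | None = None
    v_arrest: float = 2.0
    eps_path: float = 1.0
    polarity_fallback: bool = True

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2 frames")
        s = self.effective_stride
        if not (1 <= s <= self.window):
            raise ValueError("stride must satisfy 1 <= stride <= window")
        if self.v_arrest <= 0:
            raise ValueError("v_arrest must be positive")
        if self.eps_path <= 0:
            raise ValueError("eps_path must be positive")

    @property
    def effective_stride(self) -> int:
        return self.window if self.stride is None else self.stride


@dataclasses.dataclass(frozen=True)
class Tracklet:
    """A fixed-length fragment of one cell's track.

    ``start`` indexes the parent track's frames; the fragment covers the
    half-open frame range ``[start, start + W)``.
    """

    cell_id: str
    group: str
    start: int
    positions: np.ndarray          # (W, 3) µm
    dt: float                      # seconds between frames
    polarity: np.ndarray | None = None   # (W, 3) unit vectors

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValueError("positions must be a (W>=2, 3) array")
        if not np.isfinite(p).all():
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", p)

    @property
    def window(self) -> int:
        return self.positions.shape[0]


@dataclasses.dataclass(frozen=True)
class MotilityMetrics:
    displacement: float    # µm
    path_length: float     # µm
    velocity: float        # µm/min
    arrest: float          # [0, 1]
    directionality: float  # [0, 1]

    def __post_init__(self):
        if self.displacement > self.path_length + 1e-9:
            raise ValueError("displacement cannot exceed path length")


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _uniform_dt(t: np.ndarray, cell_id: str) -> float:
    diffs = np.diff(t)
    d0 = float(np.median(diffs))
    if np.any(np.abs(diffs - d0) > DT_RTOL * d0):
        raise ValueError(
            f"cell {cell_id!r} is not uniformly sampled; regularize the table first"
        )
    return d0


def decompose(table: TrackTable, cfg: TrackletConfig) -> list[Tracklet]:
    """Cut every track into tracklets of ``cfg.window`` frames.

    Per cell, tracklets start at frames 0, s, 2s, ... while a full window
    fits; cells shorter than one window yield no tracklets (logged).
    """
    W, s = cfg.window, cfg.effective_stride
    tracklets: list[Tracklet] = []
    short = 0
    for cid in table.cells:
        pos = table.positions(cid)
        t = table.times(cid)
        n = len(pos)
        if n < W:
            short += 1
            continue
        dt = _uniform_dt(t, cid)
        pol = table.polarity(cid)
        group = table.group_of(cid)
        for start in range(0, n - W + 1, s):
            tracklets.append(
                Tracklet(
                    cell_id=cid, group=group, start=start,
                    positions=pos[start:start + W], dt=dt,
                    polarity=None if pol is None else pol[start:start + W],
                )
            )
    if short:
        logger.info("decompose: %d cell(s) shorter than %d frames yielded no tracklets",
                    short, W)
    return tracklets


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _metric_arrays(P: np.ndarray, dt: np.ndarray, cfg: TrackletConfig,
                   polarity: np.ndarray | None = None):
    """Vectorized metric core over a stack of tracklets.

    Parameters
    ----------
    P : (n, W, 3) positions, dt : (n,) seconds, polarity : (n, W, 3) or None.

    Returns D, L, v, A, Gamma as (n,) arrays.
    """
    steps = np.diff(P, axis=1)                      # (n, W-1, 3)
    step_len = np.linalg.norm(steps, axis=2)        # (n, W-1)
    L = step_len.sum(axis=1)
    D = np.linalg.norm(P[:, -1] - P[:, 0], axis=1)
    minutes = (P.shape[1] - 1) * dt / 60.0
    v = L / minutes
    speeds = step_len / (dt[:, None] / 60.0)        # µm/min
    A = (speeds < cfg.v_arrest).mean(axis=1)

    gamma = np.zeros_like(L)
    moving = L >= cfg.eps_path
    gamma[moving] = np.minimum(D[moving] / L[moving], 1.0)
    if polarity is not None and cfg.polarity_fallback:
        coher = np.linalg.norm(polarity.mean(axis=1), axis=1)
        gamma[~moving] = np.minimum(coher[~moving], 1.0)
    return D, L, v, A, gamma


def summarize_track(positions: np.ndarray, dt: float,
                    cfg: TrackletConfig | None = None,
                    polarity: np.ndarray | None = None) -> MotilityMetrics:
    """Motility metrics of a whole track (or any >= 2-frame fragment)."""
    cfg = cfg or TrackletConfig()
    P = np.asarray(positions, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need at least 2 frames to summarize a track")
    if P.shape[1] == 2:
        P = np.column_stack([P, np.zeros(len(P))])
    pol = None if polarity is None else np.asarray(polarity, dtype=float)[None]
    D, L, v, A, g = _metric_arrays(P[None], np.asarray([float(dt)]), cfg, pol)
    return MotilityMetrics(float(D[0]), float(L[0]), float(v[0]), float(A[0]), float(g[0]))


def arrest_coefficient(tr: Tracklet, cfg: TrackletConfig) -> float:
    """Fraction of steps with instantaneous speed below ``cfg.v_arrest``."""
    step_len = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
    speeds = step_len / (tr.dt / 60.0)
    return float((speeds < cfg.v_arrest).mean())


def directionality(tr: Tracklet, cfg: TrackletConfig) -> float:
    """Straightness D/L, with the polarity-coherence fallback when L is tiny."""
    steps = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
    L = float(steps.sum())
    if L >= cfg.eps_path:
        D = float(np.linalg.norm(tr.positions[-1] - tr.positions[0]))
        return min(D / L, 1.0)
    if tr.polarity is not None and cfg.polarity_fallback:
        return float(min(np.linalg.norm(tr.polarity.mean(axis=0)), 1.0))
    return 0.0


def metrics_table(tracklets: list[Tracklet], cfg: TrackletConfig) -> pd.DataFrame:
    """One row of metrics per tracklet, in input order.

    Columns: cell_id, group, start, end, dt, displacement, path_length,
    velocity, arrest, directionality.
    """
    if not tracklets:
        return pd.DataFrame(columns=["cell_id", "group", "start", "end", "dt",
                                     "displacement", "path_length", "velocity",
                                     "arrest", "directionality"])
    W = tracklets[0].window
    if all(tr.window == W for tr in tracklets):
        P = np.stack([tr.positions for tr in tracklets])
        dt = np.array([tr.dt for tr in tracklets])
        if all(tr.polarity is not None for tr in tracklets):
            pol = np.stack([tr.polarity for tr in tracklets])
        else:
            pol = None
        D, L, v, A, g = _metric_arrays(P, dt, cfg, pol)
    else:  # heterogeneous windows: per-tracklet fallback
        rows = [
            _metric_arrays(tr.positions[None], np.array([tr.dt]), cfg,
                           None if tr.polarity is None else tr.polarity[None])
            for tr in tracklets
        ]
        D, L, v, A, g = (np.array([r[i][0] for r in rows]) for i in range(5))
    return pd.DataFrame({
        "cell_id": [tr.cell_id for tr in tracklets],
        "group": [tr.group for tr in tracklets],
        "start": [tr.start for tr in tracklets],
        "end": [tr.start + tr.window for tr in tracklets],
        "dt": [tr.dt for tr in tracklets],
        "displacement": D,
        "path_length": L,
        "velocity": v,
        "arrest": A,
        "directionality": g,
    })
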