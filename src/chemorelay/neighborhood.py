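"""Contact-independent influence of motile leader cells on their neighbors.

Two questions are quantified, both within a fixed radius (default 50 µm,
inclusive boundary) around a focal cell:

* does a focal cell move faster when motile leader-group cells are nearby?
  (:func:`conditional_velocity` — instantaneous velocity stratified by the
  number of motile leaders within the radius, binned 0 / 1 / >=2);
* are changes in a follower's direction of migration preceded by direction
  changes of nearby leaders?  (:func:`lead_lag_score` — fraction of follower
  turn events with a leader turn event in the preceding lag window, tested
  against a circular-shift permutation null).

"Motile" is defined through the behavioral gates: a cell counts as motile at
frame t when the tracklet covering t is in one of the motile gates
(chemokinesis or directional by default), keeping a single definition of
motility across the pipeline.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .track_io import TrackTable

logger = logging.getLogger("chemorelay")

__all__ = [
    "NeighborhoodConfig",
    "DirectionalitySeries",
    "LeadLagResult",
    "UndefinedLeadLagError",
    "ConditionalVelocityResult",
    "motile_neighbor_count",
    "conditional_velocity",
    "directionality_series",
    "lead_lag_score",
    "lead_lag_analysis",
    "neighborhood_mean_directionality",
    "common_origin",
]


@dataclasses.dataclass(frozen=True)
class NeighborhoodConfig:
    """Parameters of the neighborhood and lead-lag analyses.

    Attributes
    ----------
    radius
        Neighborhood radius in µm (boundary inclusive).
    leader_group
        Group label of the candidate leader cells.
    motile_gates
        Gate labels that count as motile.
    max_neighbor_bin
        Neighbor counts >= this value are pooled into one bin (default 2,
        i.e. bins 0, 1, >=2).
    lag_window
        Lead-lag window Delta-t in seconds; a follower turn at time t is
        "preceded" when a nearby leader turn fell in [t - Delta-t, t).
        Default 60 s (3 frames at 20 s sampling).
    turn_angle
        Heading change (degrees) that constitutes a direction-change event.
    eps_speed
        Minimum instantaneous speed (µm/min) for a step to define a heading.
    """

    radius: float = 50.0
    leader_group: str = "wt"
    motile_gates: tuple[str, ...] = ("chemokinesis", "directional")
    max_neighbor_bin: int = 2
    lag_window: float = 60.0
    turn_angle: float = 60.0
    eps_speed: float = 2.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.lag_window <= 0:
            raise ValueError("lag_window must be positive")
        if not (0 < self.turn_angle < 180):
            raise ValueError("turn_angle must lie in (0, 180) degrees")
        if self.max_neighbor_bin < 1:
            raise ValueError("max_neighbor_bin must be >= 1")


class UndefinedLeadLagError(ValueError):
    """Raised when a lead-lag score is requested with zero follower events."""


# ---------------------------------------------------------------------------
# dense frame-indexed view of a track table
# ---------------------------------------------------------------------------

class _FrameIndex:
    """Positions as a dense (cells x frames x 3) array with NaN for absence."""

    def __init__(self, table: TrackTable):
        df = table.df
        self.cells = table.cells
        self.cell_pos = {c: i for i, c in enumerate(self.cells)}
        self.frames = np.sort(df["frame"].unique())
        self.frame_pos = {f: i for i, f in enumerate(self.frames)}
        gmap = df.drop_duplicates("cell_id").set_index("cell_id")["group"]
        self.groups = gmap.loc[self.cells].to_numpy()
        C, F = len(self.cells), len(self.frames)
        self.pos = np.full((C, F, 3), np.nan)
        self.t = np.full(F, np.nan)
        ci = df["cell_id"].map(self.cell_pos).to_numpy()
        fi = df["frame"].map(self.frame_pos).to_numpy()
        self.pos[ci, fi, 0] = df["x"].to_numpy()
        self.pos[ci, fi, 1] = df["y"].to_numpy()
        self.pos[ci, fi, 2] = df["z"].to_numpy() if table.is_3d else 0.0
        self.t[fi] = df["t"].to_numpy()
        self.present = np.isfinite(self.pos[:, :, 0])

    def local_to_global(self, cell_id: str, local: np.ndarray) -> np.ndarray:
        """Map a cell's local frame indices (0..n-1) to global frame values."""
        rows = np.flatnonzero(self.present[self.cell_pos[cell_id]])
        return self.frames[rows[local]]


def _motile_flags(index: _FrameIndex, gated_metrics: pd.DataFrame,
                  cfg: NeighborhoodConfig) -> np.ndarray:
    """(cells x frames) bool: covering tracklet of a leader cell is motile.

    When tracklets overlap (stride < window) the latest-starting tracklet
    containing a frame decides.  Frames not covered by any tracklet are not
    motile.
    """
    flags = np.zeros(index.pos.shape[:2], dtype=bool)
    leaders = gated_metrics[gated_metrics["group"] == cfg.leader_group]
    for cid, sub in leaders.groupby("cell_id", sort=False):
        if cid not in index.cell_pos:
            continue
        ci = index.cell_pos[cid]
        rows = np.flatnonzero(index.present[ci])
        for _, row in sub.sort_values("start").iterrows():
            local = np.arange(int(row["start"]), int(row["end"]))
            local = local[local < len(rows)]
            flags[ci, rows[local]] = row["gate"] in cfg.motile_gates
    return flags


# ---------------------------------------------------------------------------
# motile-neighbor counting and conditional velocity
# ---------------------------------------------------------------------------

def motile_neighbor_count(table: TrackTable, gated_metrics: pd.DataFrame,
                          focal_cell: str, t: float,
                          cfg: NeighborhoodConfig) -> int:
    """Motile leader-group cells within ``cfg.radius`` of a focal cell at t.

    The focal cell never counts itself.  ``t`` must be an acquisition time
    inside the focal cell's observed range.
    """
    index = _FrameIndex(table)
    times = table.times(focal_cell)
    hit = np.flatnonzero(np.isclose(index.t, t, rtol=0, atol=1e-6))
    if hit.size == 0 or t < times[0] - 1e-6 or t > times[-1] + 1e-6:
        raise ValueError(f"t={t} is not an acquisition frame of cell {focal_cell!r}")
    fi = int(hit[0])
    ci = index.cell_pos[focal_cell]
    if not index.present[ci, fi]:
        raise ValueError(f"cell {focal_cell!r} not observed at t={t}")
    flags = _motile_flags(index, gated_metrics, cfg)
    cand = np.flatnonzero(flags[:, fi] & index.present[:, fi])
    cand = cand[cand != ci]
    if cand.size == 0:
        return 0
    d = np.linalg.norm(index.pos[cand, fi] - index.pos[ci, fi], axis=1)
    return int((d <= cfg.radius).sum())


@dataclasses.dataclass(frozen=True)
class ConditionalVelocityResult:
    records: pd.DataFrame     # cell_id, group, frame, t, velocity, n_motile, bin
    summary: pd.DataFrame     # per (group, bin): n, mean, median velocity
    tests: pd.DataFrame       # rank tests per group: 0 vs >=1 and 1 vs >=2


def _bin_label(n: int, max_bin: int) -> str:
    return str(n) if n < max_bin else f">={max_bin}"


def conditional_velocity(table: TrackTable, gated_metrics: pd.DataFrame,
                         cfg: NeighborhoodConfig) -> ConditionalVelocityResult:
    """Instantaneous velocity stratified by motile leaders within the radius.

    One record per (cell, frame) with a defined forward step; per focal
    group, Mann-Whitney rank tests compare bin 0 vs pooled >=1 neighbors and
    bin 1 vs bin >=2, with Benjamini-Hochberg adjustment across the emitted
    comparisons.  Frame-level records of one cell are strongly
    autocorrelated, so the tests run on per-cell mean velocities (each cell
    contributes at most one value per bin) to avoid pseudoreplication.
    Empty bins are reported as empty, not errors.
    """
    index = _FrameIndex(table)
    flags = _motile_flags(index, gated_metrics, cfg)
    dt = table.dt()
    C, F = index.present.shape
    recs = []
    for fi in range(F - 1):
        here = index.present[:, fi] & index.present[:, fi + 1]
        if not here.any():
            continue
        focal = np.flatnonzero(here)
        p0 = index.pos[focal, fi]
        v = np.linalg.norm(index.pos[focal, fi + 1] - p0, axis=1) / (dt / 60.0)
        motile = np.flatnonzero(flags[:, fi] & index.present[:, fi])
        if motile.size:
            tree = cKDTree(index.pos[motile, fi])
            counts = tree.query_ball_point(p0, cfg.radius, return_length=True)
            self_motile = flags[focal, fi]
            counts = counts - self_motile.astype(int)
        else:
            counts = np.zeros(len(focal), dtype=int)
        recs.append(pd.DataFrame({
            "cell_id": [index.cells[i] for i in focal],
            "group": index.groups[focal],
            "frame": index.frames[fi],
            "t": index.t[fi],
            "velocity": v,
            "n_motile": counts,
        }))
    records = pd.concat(recs, ignore_index=True) if recs else pd.DataFrame(
        columns=["cell_id", "group", "frame", "t", "velocity", "n_motile"])
    records["bin"] = [
        _bin_label(n, cfg.max_neighbor_bin) for n in records["n_motile"]
    ]
    summary = (
        records.groupby(["group", "bin"])["velocity"]
        .agg(n="size", mean="mean", median="median").reset_index()
    )
    rows = []
    for g, sub in records.groupby("group"):
        def cell_means(mask):
            return sub[mask].groupby("cell_id")["velocity"].mean().to_numpy()
        v0 = cell_means(sub["n_motile"] == 0)
        v1p = cell_means(sub["n_motile"] >= 1)
        v1 = cell_means(sub["n_motile"] == 1)
        v2p = cell_means(sub["n_motile"] >= 2)
        for name, a, b in (("0_vs_ge1", v0, v1p), ("1_vs_ge2", v1, v2p)):
            if len(a) and len(b):
                p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
            else:
                p = np.nan
            rows.append({"group": g, "comparison": name,
                         "n_a": len(a), "n_b": len(b), "p_value": p})
    tests = pd.DataFrame(rows)
    valid = tests["p_value"].notna()
    if valid.sum() >= 2:
        tests.loc[valid, "p_adj_bh"] = multipletests(
            tests.loc[valid, "p_value"], method="fdr_bh")[1]
    else:
        tests["p_adj_bh"] = tests["p_value"]
    return ConditionalVelocityResult(records=records, summary=summary, tests=tests)


# ---------------------------------------------------------------------------
# directionality over time and lead-lag
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DirectionalitySeries:
    """Sliding-window directionality and direction-change events of one cell."""

    cell_id: str
    times: np.ndarray          # (n,) seconds
    gamma: np.ndarray          # (n,) sliding-window straightness, NaN at <2-point edges
    event_frames: np.ndarray   # local frame indices of turn events
    event_times: np.ndarray    # times of turn events

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def directionality_series(positions: np.ndarray, times: np.ndarray,
                          window: int, cfg: NeighborhoodConfig,
                          cell_id: str = "") -> DirectionalitySeries:
    """Per-frame sliding-window straightness plus heading-turn events.

    The window of ``window`` frames is centered on each frame and truncated
    at the track edges.  A step defines a heading only when its speed is at
    least ``cfg.eps_speed``; an event is recorded at the frame of a defined
    step whose heading turns by more than ``cfg.turn_angle`` degrees
    relative to the previous defined heading.
    """
    P = np.asarray(positions, dtype=float)
    t = np.asarray(times, dtype=float)
    n = len(P)
    if n < window:
        raise ValueError(f"track of {n} frames is shorter than window={window}")
    h = window // 2
    gamma = np.full(n, np.nan)
    for k in range(n):
        lo = max(0, k - h)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        seg = P[lo:hi]
        steps = np.linalg.norm(np.diff(seg, axis=0), axis=1)
        L = steps.sum()
        if L > 1e-12:
            gamma[k] = min(np.linalg.norm(seg[-1] - seg[0]) / L, 1.0)
        else:
            gamma[k] = 0.0
    dt = np.diff(t)
    steps = np.diff(P, axis=0)
    speed = np.linalg.norm(steps, axis=1) / (dt / 60.0)
    defined = speed >= cfg.eps_speed
    cos_thresh = np.cos(np.deg2rad(cfg.turn_angle))
    events = []
    prev = None
    for k in np.flatnonzero(defined):
        u = steps[k] / np.linalg.norm(steps[k])
        if prev is not None and float(np.dot(u, prev)) < cos_thresh:
            events.append(k)
        prev = u
    ev = np.asarray(events, dtype=int)
    return DirectionalitySeries(cell_id=cell_id, times=t, gamma=gamma,
                                event_frames=ev, event_times=t[ev])


@dataclasses.dataclass(frozen=True)
class LeadLagResult:
    fraction: float          # follower events preceded by a nearby leader event
    p_value: float           # circular-shift permutation p-value
    n_follower_events: int
    n_leader_events: int
    null_mean: float
    null_sd: float
    n_shifts: int


def _preceded_fraction(follower_events: np.ndarray,
                       leader_trains: list[np.ndarray],
                       masks: list[np.ndarray],
                       lag: float) -> float:
    """Fraction of follower events with >=1 eligible leader event in [t-lag, t).

    ``masks[j][i]`` says whether leader train j is eligible (in radius) for
    follower event i.
    """
    hit = np.zeros(len(follower_events), dtype=bool)
    for train, mask in zip(leader_trains, masks):
        if train.size == 0:
            continue
        lo = np.searchsorted(train, follower_events - lag, side="left")
        hi = np.searchsorted(train, follower_events, side="left")
        hit |= mask & (hi > lo)
    return float(hit.mean())


def lead_lag_score(follower_events: np.ndarray,
                   leader_events: np.ndarray | list[np.ndarray],
                   cfg: NeighborhoodConfig,
                   duration: float,
                   n_shifts: int = 999,
                   seed: int = 0,
                   masks: list[np.ndarray] | None = None) -> LeadLagResult:
    """Precedence fraction of follower turn events plus a permutation p-value.

    Parameters
    ----------
    follower_events
        Times (s) of the follower's direction-change events; must be
        non-empty, otherwise :class:`UndefinedLeadLagError` is raised (an
        undefined score is not 0).
    leader_events
        One array of leader event times, or a list of per-leader trains.
    duration
        Recording length (s) used for circular shifting of leader trains.
    masks
        Optional per-train boolean eligibility (e.g. leader in radius) per
        follower event; defaults to all-eligible.

    The null distribution circularly shifts each leader train by an
    independent uniform offset (``n_shifts`` times, seeded); the p-value is
    the fraction of null scores at least as large as the observed one, with
    the +1 correction.
    """
    fe = np.asarray(follower_events, dtype=float)
    if fe.size == 0:
        raise UndefinedLeadLagError("no follower events: lead-lag score undefined")
    if isinstance(leader_events, np.ndarray):
        trains = [np.sort(np.asarray(leader_events, dtype=float))]
    else:
        trains = [np.sort(np.asarray(a, dtype=float)) for a in leader_events]
    if masks is None:
        masks = [np.ones(fe.size, dtype=bool) for _ in trains]
    n_le = int(sum(a.size for a in trains))
    obs = _preceded_fraction(fe, trains, masks, cfg.lag_window)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shifts)
    for s in range(n_shifts):
        shifted = [np.sort((a + rng.uniform(0, duration)) % duration) for a in trains]
        null[s] = _preceded_fraction(fe, shifted, masks, cfg.lag_window)
    p = (1.0 + np.sum(null >= obs - 1e-12)) / (n_shifts + 1.0)
    return LeadLagResult(fraction=obs, p_value=float(p),
                         n_follower_events=int(fe.size), n_leader_events=n_le,
                         null_mean=float(null.mean()), null_sd=float(null.std()),
                         n_shifts=n_shifts)


def lead_lag_analysis(table: TrackTable, cfg: NeighborhoodConfig,
                      window: int = 10, n_shifts: int = 999,
                      seed: int = 0) -> LeadLagResult | None:
    """Pooled lead-lag score of all follower cells against nearby leaders.

    Turn events are computed per cell with :func:`directionality_series`;
    for each follower event at time t, a leader train is eligible when that
    leader lies within ``cfg.radius`` of the follower at t.  Returns ``None``
    (with a log message) when no follower has any turn event.
    """
    index = _FrameIndex(table)
    dt = table.dt()
    series: dict[str, DirectionalitySeries] = {}
    for cid in table.cells:
        pos = table.positions(cid)
        if len(pos) < window:
            continue
        series[cid] = directionality_series(pos, table.times(cid), window, cfg, cid)
    leader_ids = [c for c in series if table.group_of(c) == cfg.leader_group]
    follower_ids = [c for c in series
                    if table.group_of(c) != cfg.leader_group
                    and series[c].event_times.size > 0]
    if not follower_ids:
        logger.info("lead_lag_analysis: no follower turn events; score undefined")
        return None
    fe_all, masks_per_leader = [], [[] for _ in leader_ids]
    for fid in follower_ids:
        s = series[fid]
        fpos_rows = np.flatnonzero(index.present[index.cell_pos[fid]])
        for k, t_ev in zip(s.event_frames, s.event_times):
            fe_all.append(t_ev)
            fi = fpos_rows[k]
            p_f = index.pos[index.cell_pos[fid], fi]
            for j, lid in enumerate(leader_ids):
                li = index.cell_pos[lid]
                if index.present[li, fi]:
                    d = float(np.linalg.norm(index.pos[li, fi] - p_f))
                    masks_per_leader[j].append(d <= cfg.radius)
                else:
                    masks_per_leader[j].append(False)
    fe = np.asarray(fe_all)
    trains = [series[lid].event_times for lid in leader_ids]
    masks = [np.asarray(m, dtype=bool) for m in masks_per_leader]
    duration = float(index.t[-1] - index.t[0] + dt)
    return lead_lag_score(fe, trains, cfg, duration, n_shifts=n_shifts,
                          seed=seed, masks=masks)


def neighborhood_mean_directionality(table: TrackTable, focal_cell: str,
                                     cfg: NeighborhoodConfig,
                                     window: int = 10) -> pd.DataFrame:
    """Mean sliding-window directionality of all in-radius neighbors per frame.

    Neighbors are cells of any group within ``cfg.radius`` of the focal cell
    (focal excluded); frames with no neighbor yield NaN (a gap).  Returns a
    frame-indexed table with columns t and mean_directionality.
    """
    index = _FrameIndex(table)
    if focal_cell not in index.cell_pos:
        raise KeyError(focal_cell)
    gammas = np.full(index.present.shape, np.nan)
    for cid in table.cells:
        pos = table.positions(cid)
        if len(pos) < 2:
            continue
        w = min(window, len(pos))
        s = directionality_series(pos, table.times(cid), w, cfg, cid)
        rows = np.flatnonzero(index.present[index.cell_pos[cid]])
        gammas[index.cell_pos[cid], rows] = s.gamma
    ci = index.cell_pos[focal_cell]
    out_frames = np.flatnonzero(index.present[ci])
    mean_g = np.full(len(out_frames), np.nan)
    for k, fi in enumerate(out_frames):
        others = np.flatnonzero(index.present[:, fi])
        others = others[others != ci]
        if others.size == 0:
            continue
        d = np.linalg.norm(index.pos[others, fi] - index.pos[ci, fi], axis=1)
        near = others[d <= cfg.radius]
        if near.size == 0:
            continue
        vals = gammas[near, fi]
        if np.isfinite(vals).any():
            mean_g[k] = np.nanmean(vals)
    return pd.DataFrame({"frame": index.frames[out_frames],
                         "t": index.t[out_frames],
                         "mean_directionality": mean_g})


def common_origin(table: TrackTable) -> pd.DataFrame:
    """Translate every track so its first position is the origin.

    Returns a long table (cell_id, group, frame, t, x, y, z, displacement)
    where displacement is the distance from the track's own start — the
    machine-readable twin of a common-origin track plot.
    """
    out = []
    for cid in table.cells:
        pos = table.positions(cid)
        rel = pos - pos[0]
        out.append(pd.DataFrame({
            "cell_id": cid, "group": table.group_of(cid),
            "frame": np.arange(len(pos)), "t": table.times(cid),
            "x": rel[:, 0], "y": rel[:, 1], "z": rel[:, 2],
            "displacement": np.linalg.norm(rel, axis=1),
        }))
    return pd.concat(out, ignore_index=True)
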