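"""Agent-based leader-follower chemotaxis simulator.

The model embodies a paracrine relay mechanism for contact-independent,
cell-to-cell-induced migration of lymphoma cells in a 3D chemokine chamber:

* **leaders** ("wt", scavenger-receptor competent) chemotax up a CXCL12
  gradient as a persistent biased random walk, alternating run and pause
  phases; while exposed to sufficient CXCL12 they secrete a short-range
  attractant cue (LTB4), modeled as a quasi-steady exponential field around
  each secreting leader;
* **followers** ("ko", scavenger-receptor deficient) are intrinsically
  almost immobile — positional jitter only.  A follower is *activated* at a
  frame when the local LTB4 level reaches a threshold AND local CXCL12 is
  present (a hard synergy gate: the cue alone does not move cells); while
  activated it migrates with partially restored speed and gradient bias.

Perturbations map onto experimental arms: PTX (Gi-protein block) removes a
cell's chemotactic response and a leader's cue secretion; a C-terminally
truncated scavenger receptor (``ackr3_deltaC``) leaves leaders motile but
unable to chemotax or secrete the cue; knocking out the cue receptor
(``blt1r_ko``) removes the follower response while secretion persists.

Every quantitative choice (half-normal step lengths, exponential cue
kernel, threshold activation, reflecting boundaries, linear gradient) is a
declared surrogate for a verbal model; the simulator's job is to produce
track tables with the qualitative population structure of the experiment,
not mechanistic fidelity.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import erf

from .track_io import TrackTable

logger = logging.getLogger("chemorelay")

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "AgentState",
    "PRESETS",
    "preset",
    "cxcl12_field",
    "ltb4_field",
    "step",
    "simulate",
    "transwell_surrogate",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the leader-follower agent model.

    Geometry and timing follow the chamber experiment being emulated: a
    millimetre-scale volume, a CXCL12 gradient along x, 6 h recordings at
    20 s frame intervals.  Speeds are in µm/min, lengths in µm, times in s.

    Attributes
    ----------
    arena
        Box dimensions (x, y, z) in µm.
    profile, c0, c_min
        Gradient shape (``linear`` or ``erf``), nominal source concentration
        (arbitrary units; 400 matches a 400 nM source) and the minimum local
        CXCL12 for a leader to secrete the cue.
    leader_speed, persistence, chemotactic_bias
        Run-phase half-normal speed scale sigma_v, heading persistence p in
        [0, 1) and gradient bias chi_wt in [0, 1] of unperturbed leaders.
    p_stop, p_go
        Per-frame run->pause and pause->run switching probabilities of
        leaders (intermittent migration; at the defaults leaders spend about
        half the time paused with multi-minute dwell times).
    follower_speed, pause_speed
        Jitter speed scales of intrinsically immobile followers and of
        paused leaders; both well below the arrest threshold of the
        analysis, and jitter steps are isotropic (no heading persistence).
    ltb4_range, ltb4_source, ltb4_threshold
        Exponential cue kernel q * exp(-d / lambda) per secreting leader and
        the follower activation threshold l*.  Defaults give an effective
        reach -lambda * ln(l*/q) of just under 50 µm.
    rescued_speed, rescued_bias
        Speed scale sigma_v1 and gradient bias chi_syn of an activated
        follower (partial rescue: slower and less biased than leaders).
    ptx_leaders, ptx_followers, ackr3_deltaC, blt1r_ko
        Perturbation flags, see module docstring.
    scavenging_sink
        Optional local CXCL12 depletion around leaders (exploratory, off by
        default: the relay cue, not gradient reshaping, is the modeled
        route).
    deposit_mode, deposit_tau
        Optional "deposit" variant of the cue field: a leader entering a
        pause leaves a decaying point cue (time constant deposit_tau, s) at
        that spot instead of carrying the field with it.
    """

    arena: tuple[float, float, float] = (1000.0, 500.0, 100.0)
    gradient_axis: int = 0
    profile: str = "linear"
    c0: float = 400.0
    c_min: float = 20.0
    n_leaders: int = 100
    n_followers: int = 100
    dt: float = 20.0
    duration: float = 21600.0
    leader_speed: float = 4.0
    persistence: float = 0.2
    chemotactic_bias: float = 0.25
    p_stop: float = 0.02
    p_go: float = 0.02
    follower_speed: float = 0.3
    pause_speed: float = 0.3
    ltb4_range: float = 15.0
    ltb4_source: float = 1.0
    ltb4_threshold: float = 0.0369
    rescued_speed: float = 2.0
    rescued_bias: float = 0.2
    ptx_leaders: bool = False
    ptx_followers: bool = False
    ackr3_deltaC: bool = False
    blt1r_ko: bool = False
    scavenging_sink: float = 0.0
    deposit_mode: bool = False
    deposit_tau: float = 120.0
    seed: int = 0

    def __post_init__(self):
        errors = []
        if any(a <= 0 for a in self.arena):
            errors.append("arena dimensions must be positive")
        if self.gradient_axis not in (0, 1, 2):
            errors.append("gradient_axis must be 0, 1 or 2")
        if self.profile not in ("linear", "erf"):
            errors.append("profile must be 'linear' or 'erf'")
        if self.dt <= 0 or self.duration <= 0:
            errors.append("dt and duration must be positive")
        elif abs(self.duration / self.dt - round(self.duration / self.dt)) > 1e-9:
            errors.append("dt must divide duration")
        if self.n_leaders < 0 or self.n_followers < 0:
            errors.append("agent counts must be non-negative")
        if self.n_leaders + self.n_followers == 0:
            errors.append("at least one agent is required")
        for name in ("c0", "leader_speed", "follower_speed", "pause_speed",
                     "rescued_speed", "ltb4_range", "ltb4_source", "ltb4_threshold"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if not (0 <= self.persistence < 1):
            errors.append("persistence must lie in [0, 1)")
        for name in ("chemotactic_bias", "rescued_bias", "p_stop", "p_go"):
            if not (0 <= getattr(self, name) <= 1):
                errors.append(f"{name} must lie in [0, 1]")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    @property
    def ltb4_reach(self) -> float:
        """Distance at which the single-leader cue falls to the threshold."""
        return self.ltb4_range * np.log(self.ltb4_source / self.ltb4_threshold)


PRESETS: dict[str, dict] = {
    "ko_alone": {"n_leaders": 0, "n_followers": 100},
    "wt_alone": {"n_leaders": 100, "n_followers": 0},
    "mixed_1to1": {},
    "mixed_ptx_wt": {"ptx_leaders": True},
    "mixed_ptx_ko": {"ptx_followers": True},
    "mixed_deltaC": {"ackr3_deltaC": True},
    "mixed_blt1rko": {"blt1r_ko": True},
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named experimental-arm configuration (mixed arms are 1:1)."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return SimulationConfig(seed=seed, **{**base, **overrides})


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

def _inside(pos: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    box = np.asarray(cfg.arena)
    return np.all((pos >= 0) & (pos <= box), axis=-1)


def cxcl12_field(position: np.ndarray, cfg: SimulationConfig,
                 leader_positions: np.ndarray | None = None) -> np.ndarray:
    """Chemokine concentration at one or more positions (arbitrary units).

    Monotone non-decreasing along the gradient axis; ``linear`` rises from 0
    at the low edge to ``c0`` at the high edge, ``erf`` is a sigmoidal
    diffusion-like front centered mid-arena.  Positions outside the arena
    raise.  When ``scavenging_sink > 0`` and leader positions are given, a
    local exponential depletion around each leader is subtracted
    (exploratory option, off by default).
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    if not _inside(pos, cfg).all():
        raise ValueError("position outside arena")
    xi = pos[:, cfg.gradient_axis]
    L = cfg.arena[cfg.gradient_axis]
    if cfg.profile == "linear":
        c = cfg.c0 * xi / L
    else:
        c = cfg.c0 * 0.5 * (1.0 + erf((xi - L / 2) / (L / 4)))
    if cfg.scavenging_sink > 0 and leader_positions is not None and len(leader_positions):
        d = cdist(pos, np.atleast_2d(leader_positions))
        c = np.maximum(c - cfg.scavenging_sink * np.exp(-d / cfg.ltb4_range).sum(axis=1), 0.0)
    return c if np.asarray(position).ndim > 1 else float(c[0])


def ltb4_field(position: np.ndarray,
               source_positions: np.ndarray,
               secreting: np.ndarray | None = None,
               cfg: SimulationConfig | None = None,
               weights: np.ndarray | None = None) -> np.ndarray:
    """Cue level at one or more positions: sum of q * exp(-d / lambda).

    ``source_positions`` are leader (or deposit) locations; ``secreting``
    optionally masks the currently eligible sources; ``weights`` scales each
    source (used by deposit decay).  Zero when no source secretes.
    """
    if cfg is None:
        raise ValueError("cfg is required")
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    src = np.atleast_2d(np.asarray(source_positions, dtype=float)) \
        if len(source_positions) else np.empty((0, 3))
    if secreting is not None:
        src = src[np.asarray(secreting, dtype=bool)]
        if weights is not None:
            weights = np.asarray(weights)[np.asarray(secreting, dtype=bool)]
    if len(src) == 0:
        out = np.zeros(len(pos))
    else:
        d = cdist(pos, src)
        w = cfg.ltb4_source if weights is None else cfg.ltb4_source * weights
        out = (w * np.exp(-d / cfg.ltb4_range)).sum(axis=1)
    return out if np.asarray(position).ndim > 1 else float(out[0])


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AgentState:
    """Mutable per-frame state of the whole agent population."""

    pos: np.ndarray          # (n, 3) µm
    heading: np.ndarray      # (n, 3) unit vectors
    is_leader: np.ndarray    # (n,) bool
    running: np.ndarray      # (n,) bool; leader run/pause phase
    active: np.ndarray       # (n,) bool; follower cue activation
    deposits: list           # [(position, age_s)] when deposit_mode


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n[n < 1e-12] = 1.0
    return v / n


def _reflect(pos: np.ndarray, heading: np.ndarray, cfg: SimulationConfig):
    box = np.asarray(cfg.arena)
    for ax in range(3):
        low = pos[:, ax] < 0
        pos[low, ax] = -pos[low, ax]
        heading[low, ax] = -heading[low, ax]
        high = pos[:, ax] > box[ax]
        pos[high, ax] = 2 * box[ax] - pos[high, ax]
        heading[high, ax] = -heading[high, ax]
    np.clip(pos, 0, box, out=pos)
    return pos, heading


def step(state: AgentState, cfg: SimulationConfig,
         rng: np.random.Generator) -> AgentState:
    """Advance every agent by one frame (mutates and returns ``state``).

    Movement is a persistent biased random walk: the new heading mixes the
    previous heading (weight p), the gradient direction (weight
    (1 - p) * chi) and a uniform random unit vector; the step length is
    half-normal with scale sigma * dt.  Jittering agents (paused leaders,
    inactive followers) draw isotropic headings with no persistence.  Cue
    secretion and follower activation are evaluated before moving.
    """
    n = len(state.pos)
    leaders = state.is_leader
    followers = ~leaders
    grad_dir = np.zeros(3)
    grad_dir[cfg.gradient_axis] = 1.0

    c_local = cxcl12_field(state.pos, cfg,
                           leader_positions=state.pos[leaders]
                           if cfg.scavenging_sink > 0 else None)

    # cue sources: PTX'd or C-terminally truncated leaders never secrete;
    # secretion is CXCL12-gated and independent of the responders' receptor
    can_secrete = leaders & ~(cfg.ptx_leaders | cfg.ackr3_deltaC)
    secreting = can_secrete & (c_local >= cfg.c_min)

    if cfg.deposit_mode:
        # cues live where a leader entered a pause, decaying exponentially
        state.deposits = [(p, age + cfg.dt) for p, age in state.deposits
                          if age + cfg.dt <= 5 * cfg.deposit_tau]
        src = np.array([p for p, _ in state.deposits]).reshape(-1, 3)
        w = np.exp(-np.array([age for _, age in state.deposits]) / cfg.deposit_tau)
        cue = ltb4_field(state.pos, src, None, cfg,
                         weights=w if len(w) else None)
    else:
        cue = ltb4_field(state.pos, state.pos[leaders], secreting[leaders], cfg)

    # follower activation: hard synergy gate — cue above threshold AND local
    # chemokine present AND an intact Gi response to the cue
    state.active = (followers & (cue >= cfg.ltb4_threshold) & (c_local > 0)
                    & (not cfg.blt1r_ko) & (not cfg.ptx_followers))

    # leader run/pause switching
    if leaders.any():
        u = rng.random(int(leaders.sum()))
        run = state.running[leaders]
        flip = np.where(run, u < cfg.p_stop, u < cfg.p_go)
        new_run = run ^ flip
        if cfg.deposit_mode:
            stopped = run & ~new_run
            for p in state.pos[leaders][stopped & secreting[leaders]]:
                state.deposits.append((p.copy(), 0.0))
        state.running[leaders] = new_run

    # per-agent speed scale, bias and persistence
    sigma = np.full(n, cfg.follower_speed)
    chi = np.zeros(n)
    pers = np.zeros(n)
    lr = leaders & state.running
    sigma[lr] = cfg.leader_speed
    pers[lr] = cfg.persistence
    chi[lr] = 0.0 if (cfg.ptx_leaders or cfg.ackr3_deltaC) else cfg.chemotactic_bias
    lp = leaders & ~state.running
    sigma[lp] = cfg.pause_speed
    fa = followers & state.active
    sigma[fa] = cfg.rescued_speed
    chi[fa] = cfg.rescued_bias
    pers[fa] = cfg.persistence

    u_rand = _unit(rng.standard_normal((n, 3)))
    target = chi[:, None] * grad_dir + (1 - chi[:, None]) * u_rand
    heading = _unit(pers[:, None] * state.heading + (1 - pers[:, None]) * target)
    step_len = np.abs(rng.standard_normal(n)) * sigma * (cfg.dt / 60.0)
    pos = state.pos + step_len[:, None] * heading
    state.pos, state.heading = _reflect(pos, heading, cfg)
    return state


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Simulator-side truth: agent types, flags and per-frame activation."""

    agents: pd.DataFrame       # cell_id, type, perturbation flags
    activation: pd.DataFrame   # cell_id, frame, active (followers only)
    config: SimulationConfig


def simulate(cfg: SimulationConfig) -> tuple[TrackTable, GroundTruth]:
    """Run the agent model and return a track table plus ground truth.

    Initial positions are uniform in the arena; leaders start in the run
    phase with random headings, followers inactive.  Output groups are
    ``wt`` (leaders) and ``ko`` (followers).  Identical config and seed give
    bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_leaders + cfg.n_followers
    is_leader = np.zeros(n, dtype=bool)
    is_leader[:cfg.n_leaders] = True
    ids = ([f"wt_{i:04d}" for i in range(cfg.n_leaders)]
           + [f"ko_{i:04d}" for i in range(cfg.n_followers)])
    box = np.asarray(cfg.arena)
    state = AgentState(
        pos=rng.random((n, 3)) * box,
        heading=_unit(rng.standard_normal((n, 3))),
        is_leader=is_leader,
        running=is_leader.copy(),
        active=np.zeros(n, dtype=bool),
        deposits=[],
    )
    n_frames = cfg.n_frames
    traj = np.empty((n_frames, n, 3))
    act = np.zeros((n_frames, n), dtype=bool)
    traj[0] = state.pos
    for k in range(1, n_frames):
        step(state, cfg, rng)
        traj[k] = state.pos
        act[k] = state.active

    frames = np.arange(n_frames)
    df = pd.DataFrame({
        "cell_id": np.repeat(ids, n_frames),
        "group": np.repeat(np.where(is_leader, "wt", "ko"), n_frames),
        "frame": np.tile(frames, n),
        "t": np.tile(frames * cfg.dt, n),
        "x": traj[:, :, 0].T.ravel(),
        "y": traj[:, :, 1].T.ravel(),
        "z": traj[:, :, 2].T.ravel(),
    })
    table = TrackTable(df, validate=False)

    agents = pd.DataFrame({
        "cell_id": ids,
        "type": np.where(is_leader, "leader", "follower"),
        "ptx": np.where(is_leader, cfg.ptx_leaders, cfg.ptx_followers),
        "ackr3_deltaC": is_leader & cfg.ackr3_deltaC,
        "blt1r_ko": cfg.blt1r_ko,
    })
    f_idx = np.flatnonzero(~is_leader)
    activation = pd.DataFrame({
        "cell_id": np.repeat([ids[i] for i in f_idx], n_frames),
        "frame": np.tile(frames, len(f_idx)),
        "active": act[:, f_idx].T.ravel(),
    })
    return table, GroundTruth(agents=agents, activation=activation, config=cfg)


# ---------------------------------------------------------------------------
# transwell surrogate
# ---------------------------------------------------------------------------

def transwell_surrogate(table: TrackTable, plane: float | None = None,
                        axis: int = 0) -> pd.DataFrame:
    """Percent of each group's input that crossed a plane by the last frame.

    The plane is orthogonal to the gradient axis (default three quarters of
    the way along it).  "Input" are the agents starting on the near (low)
    side of the plane; the readout is the percentage of those whose final
    position lies at or beyond the plane.  If a group has no near-side
    agents, every cell already passed the plane and 100% is reported.
    """
    if plane is None:
        plane = 0.75 * (table.df[["x", "y", "z"][axis]].max())
    coord = ["x", "y", "z"][axis]
    rows = []
    for g in table.groups:
        sub = table.df[table.df["group"] == g]
        first = sub.groupby("cell_id")[coord].first()
        last = sub.groupby("cell_id")[coord].last()
        near = first < plane
        if near.sum() == 0:
            pct = 100.0
        else:
            pct = 100.0 * (last[near] >= plane).mean()
        rows.append({"group": g, "plane": plane, "n_input": int(near.sum()),
                     "percent_crossed": pct})
    return pd.DataFrame(rows)
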