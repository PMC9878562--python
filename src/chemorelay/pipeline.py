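"""One-command orchestration of the full track-analysis pipeline.

``run`` executes the stages in fixed order — ingest (simulate or read),
regularize, tracklet decomposition and metrics, gate counting, neighborhood
and lead-lag analyses — persisting every intermediate table so every number
in the report can be recomputed from disk.  A single global seed drives all
seeded stages through fixed offsets (simulation +0, gate sampling +1,
permutation null +2), so identical configuration yields byte-identical
report bodies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .track_io import TrackTable, read_tracks, write_tracks, regularize, fill_gaps
from .motility import TrackletConfig, decompose, metrics_table
from .gating import GateConfig, classify_table, gate_counts, gate_scatter_export
from .neighborhood import (NeighborhoodConfig, conditional_velocity,
                           lead_lag_analysis, common_origin)
from .simulate import SimulationConfig, preset, simulate, PRESETS

logger = logging.getLogger("chemorelay")

__all__ = ["RunConfig", "RunReport", "ConfigError", "PipelineStageError",
           "validate_config", "run"]

_SEED_OFFSETS = {"simulation": 0, "gating": 1, "permutation": 2}
_MOD = 2**31


class ConfigError(ValueError):
    """Carries the full list of configuration violations, not just the first."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Resolved pipeline configuration (exactly one input source)."""

    input_path: str | None = None
    preset: str | None = None
    dialect: str = "canonical"
    default_group: str | None = None
    dt_target: float | None = None
    max_gap: int = 2
    tracklet: TrackletConfig = dataclasses.field(default_factory=TrackletConfig)
    gate: GateConfig = dataclasses.field(default_factory=GateConfig)
    neighborhood: NeighborhoodConfig = dataclasses.field(default_factory=NeighborhoodConfig)
    simulation: SimulationConfig | None = None
    lead_lag: bool = True
    lead_lag_shifts: int = 999
    out_dir: str = "chemorelay_out"
    fmt: str = "csv"
    log_level: str = "INFO"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSETS[stage]) % _MOD


def validate_config(raw) -> RunConfig:
    """Build a fully resolved :class:`RunConfig` from YAML text/path/dict.

    Every violation found is collected and reported together in a
    :class:`ConfigError`; an empty config yields the fully defaulted run.
    """
    if isinstance(raw, (str, Path)) and Path(str(raw)).exists():
        raw = Path(raw).read_text()
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config key(s): {sorted(unknown)}")
    kw = {k: v for k, v in raw.items() if k in known}

    if kw.get("input_path") and kw.get("preset"):
        errors.append("input_path and preset are mutually exclusive; give exactly one")
    if kw.get("preset") and kw["preset"] not in PRESETS:
        errors.append(f"unknown preset {kw['preset']!r}; available: {sorted(PRESETS)}")
    if kw.get("fmt", "csv") not in ("csv", "tsv"):
        errors.append("fmt must be 'csv' or 'tsv'")
    dt_target = kw.get("dt_target")
    if dt_target is not None and dt_target <= 0:
        errors.append("dt_target must be positive")

    for section, cls in (("tracklet", TrackletConfig), ("gate", GateConfig),
                         ("neighborhood", NeighborhoodConfig)):
        val = kw.get(section)
        if val is None:
            continue
        if isinstance(val, dict):
            try:
                kw[section] = cls(**val)
            except (TypeError, ValueError) as e:
                errors.append(f"{section}: {e}")
        elif not isinstance(val, cls):
            errors.append(f"{section} must be a mapping or {cls.__name__}")
    # simulation: preset base merged with explicit overrides
    sim_raw = kw.get("simulation")
    if isinstance(sim_raw, SimulationConfig):
        sim_raw = {f.name: getattr(sim_raw, f.name)
                   for f in dataclasses.fields(SimulationConfig)}
    if sim_raw is not None and not isinstance(sim_raw, dict):
        errors.append("simulation must be a mapping or SimulationConfig")
        sim_raw = None
    if kw.get("preset") in PRESETS or sim_raw is not None:
        base = dict(PRESETS.get(kw.get("preset"), {}))
        base.update(sim_raw or {})
        try:
            kw["simulation"] = SimulationConfig(**base)
        except (TypeError, ValueError) as e:
            errors.append(f"simulation: {e}")
            kw.pop("simulation", None)
    if errors:
        raise ConfigError(errors)
    cfg = RunConfig(**kw)
    # propagate the global seed into the seeded sub-configs
    gate = dataclasses.replace(cfg.gate, seed=cfg.stage_seed("gating"))
    sim = cfg.simulation
    if sim is not None:
        sim = dataclasses.replace(sim, seed=cfg.stage_seed("simulation"))
    return dataclasses.replace(cfg, gate=gate, simulation=sim)


@dataclasses.dataclass(frozen=True)
class RunReport:
    """Structured results of one pipeline run (JSON-serializable body)."""

    body: dict

    def to_json(self) -> str:
        return json.dumps(self.body, indent=2, sort_keys=True)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def _track_summaries(table: TrackTable, tracklet_cfg: TrackletConfig) -> dict:
    from .motility import summarize_track
    rows = {}
    for g in table.groups:
        D, L, V = [], [], []
        for cid in table.cells:
            if table.group_of(cid) != g:
                continue
            pos = table.positions(cid)
            if len(pos) < 2:
                continue
            m = summarize_track(pos, table.dt(cid), tracklet_cfg)
            D.append(m.displacement); L.append(m.path_length); V.append(m.velocity)
        def stats(v):
            a = np.asarray(v)
            return {"n": int(a.size), "mean": float(a.mean()),
                    "median": float(np.median(a)),
                    "q25": float(np.quantile(a, 0.25)),
                    "q75": float(np.quantile(a, 0.75))}
        rows[g] = {"displacement": stats(D), "path_length": stats(L),
                   "velocity": stats(V)}
    return rows


def run(cfg: RunConfig) -> RunReport:
    """Execute the pipeline; persist intermediates and return the report.

    Any stage error aborts the run with the stage name; a failure marker is
    left next to whatever partial outputs were already written.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = "," if cfg.fmt == "csv" else "\t"
    ext = cfg.fmt
    logging.basicConfig(level=cfg.log_level)
    stage = "setup"

    def save(df: pd.DataFrame, name: str):
        df.to_csv(out / f"{name}.{ext}", sep=sep, index=False, float_format="%.12g")

    try:
        stage = "ingest"
        if cfg.preset is not None or cfg.simulation is not None:
            sim_cfg = cfg.simulation
            logger.info("stage=ingest simulating preset=%s n_agents=%d",
                        cfg.preset, sim_cfg.n_leaders + sim_cfg.n_followers)
            table, truth = simulate(sim_cfg)
            save(truth.agents, "ground_truth_agents")
            save(truth.activation, "ground_truth_activation")
            (out / "simulation_config.json").write_text(
                json.dumps(_jsonable(sim_cfg), indent=2, sort_keys=True))
        elif cfg.input_path is not None:
            logger.info("stage=ingest reading %s (dialect=%s)", cfg.input_path, cfg.dialect)
            table = read_tracks(cfg.input_path, dialect=cfg.dialect,
                                default_group=cfg.default_group)
            table = fill_gaps(table, cfg.max_gap)
            truth = None
        else:
            raise ValueError("no input source: set input_path or preset")
        write_tracks(table, out / f"tracks.{ext}")

        stage = "regularize"
        if cfg.dt_target is not None:
            table = regularize(table, cfg.dt_target)
            write_tracks(table, out / f"tracks_regularized.{ext}")
        dt = table.dt()
        logger.info("stage=regularize n_cells=%d dt=%gs", table.n_cells, dt)

        stage = "tracklets"
        tracklets = decompose(table, cfg.tracklet)
        metrics = metrics_table(tracklets, cfg.tracklet)
        save(metrics, "tracklet_metrics")
        logger.info("stage=tracklets n_tracklets=%d", len(metrics))

        stage = "gating"
        gated_all = classify_table(metrics, cfg.gate)
        save(gated_all, "tracklet_gates")
        assignment = gate_counts(metrics, cfg.gate)
        counts = assignment.counts.reset_index()
        save(counts, "gate_counts")
        save(gate_scatter_export(assignment), "gate_scatter")
        (out / "gate_config.json").write_text(
            json.dumps(_jsonable(assignment.metadata), indent=2, sort_keys=True))
        logger.info("stage=gating counts=%s", assignment.counts.to_dict())

        stage = "neighborhood"
        save(common_origin(table), "common_origin")
        neigh = None
        if cfg.neighborhood.leader_group in table.groups:
            neigh = conditional_velocity(table, gated_all, cfg.neighborhood)
            save(neigh.records, "neighborhood_records")
            save(neigh.summary, "conditional_velocity_summary")
            save(neigh.tests, "conditional_velocity_tests")

        stage = "lead_lag"
        lead_lag = None
        if (cfg.lead_lag and cfg.neighborhood.leader_group in table.groups
                and len(table.groups) > 1):
            lead_lag = lead_lag_analysis(
                table, cfg.neighborhood, window=cfg.tracklet.window,
                n_shifts=cfg.lead_lag_shifts, seed=cfg.stage_seed("permutation"))

        stage = "report"
        from . import __version__
        body = {
            "version": __version__,
            "seed": cfg.seed,
            "stage_seeds": {s: cfg.stage_seed(s) for s in _SEED_OFFSETS},
            "config": {
                "tracklet": _jsonable(cfg.tracklet),
                "gate": _jsonable(cfg.gate),
                "neighborhood": _jsonable(cfg.neighborhood),
                "simulation": _jsonable(cfg.simulation) if cfg.simulation else None,
                "preset": cfg.preset,
                "input_path": cfg.input_path,
                "dt": dt,
            },
            "track_summaries": _track_summaries(table, cfg.tracklet),
            "gate_counts": {g: {k: int(v) for k, v in row.items()}
                            for g, row in assignment.counts.iterrows()},
            "conditional_velocity": None if neigh is None else {
                "summary": neigh.summary.to_dict(orient="records"),
                "tests": _jsonable(neigh.tests.to_dict(orient="records")),
            },
            "lead_lag": None if lead_lag is None else _jsonable(lead_lag),
        }
        report = RunReport(body=_jsonable(body))
        (out / "report.json").write_text(report.to_json())
        return report
    except Exception as e:
        (out / "FAILED").write_text(f"stage={stage}\nerror={e}\n")
        if isinstance(e, PipelineStageError):
            raise
        raise PipelineStageError(stage, e) from e
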