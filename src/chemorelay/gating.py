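"""Four-gate behavioral classification on the (arrest, directionality) plane.

Each tracklet falls into exactly one quadrant of the unit square, split by an
arrest threshold ``a*`` and a directionality threshold ``d*``:

==================  ==============  ====================
gate                arrest          directionality
==================  ==============  ====================
``chemokinesis``    low  (A < a*)   low  (Gamma < d*)
``immobile``        high (A >= a*)  low
``polarized``       high            high (Gamma >= d*)
``directional``     low             high
==================  ==============  ====================

"polarized" captures cells that protrude lamellipods — hence are visibly
polarized — but barely translocate; "directional" captures pronounced
directed migration.  Per-group count tables are produced from seeded samples
of a fixed number of tracklets (default 1000) drawn without replacement, so
gate counts are comparable across groups and runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "GATE_LABELS",
    "GateConfig",
    "GateAssignment",
    "classify",
    "classify_table",
    "gate_counts",
    "gate_scatter_export",
]

GATE_LABELS = ("chemokinesis", "immobile", "polarized", "directional")


@dataclasses.dataclass(frozen=True)
class GateConfig:
    """Gate thresholds and the sampling protocol for count tables.

    Thresholds are strictly inside (0, 1); the boundary convention is
    ">= threshold counts as high" on both axes.  Defaults a* = 0.6,
    d* = 0.5 place pure-stationary and pure-ballistic archetypes deep inside
    the immobile and directional gates respectively.
    """

    a_star: float = 0.6
    d_star: float = 0.5
    sample_n: int = 1000
    seed: int = 0
    allow_short_groups: bool = False

    def __post_init__(self):
        if not (0 < self.a_star < 1):
            raise ValueError("a_star must lie strictly inside (0, 1)")
        if not (0 < self.d_star < 1):
            raise ValueError("d_star must lie strictly inside (0, 1)")
        if self.sample_n < 1:
            raise ValueError("sample_n must be >= 1")


@dataclasses.dataclass(frozen=True)
class GateAssignment:
    """A seeded per-group sample of tracklets with gate labels and counts."""

    sample: pd.DataFrame          # sampled metric rows + 'gate' column
    counts: pd.DataFrame          # index: group, columns: GATE_LABELS
    config: GateConfig

    @property
    def metadata(self) -> dict:
        return {
            "a_star": self.config.a_star,
            "d_star": self.config.d_star,
            "sample_n": self.config.sample_n,
            "seed": self.config.seed,
            "labels": list(GATE_LABELS),
        }


def classify(arrest: float, directionality: float, cfg: GateConfig) -> str:
    """Gate label of a single (A, Gamma) pair."""
    high_a = arrest >= cfg.a_star
    high_d = directionality >= cfg.d_star
    if high_a:
        return "polarized" if high_d else "immobile"
    return "directional" if high_d else "chemokinesis"


def classify_table(metrics: pd.DataFrame, cfg: GateConfig) -> pd.DataFrame:
    """Return a copy of a metrics table with a ``gate`` column appended."""
    high_a = metrics["arrest"].to_numpy() >= cfg.a_star
    high_d = metrics["directionality"].to_numpy() >= cfg.d_star
    gate = np.where(high_a,
                    np.where(high_d, "polarized", "immobile"),
                    np.where(high_d, "directional", "chemokinesis"))
    out = metrics.copy()
    out["gate"] = gate
    return out


def _sample_group(sub: pd.DataFrame, cfg: GateConfig, group_index: int) -> pd.DataFrame:
    """Deterministic, platform-stable sample of one group.

    Rows are sorted by (cell_id, start) and shuffled with a generator seeded
    from (seed, group index in sorted group order); the first ``sample_n``
    rows form the sample.  This makes samples independent of input row order.
    """
    sub = sub.sort_values(["cell_id", "start"], kind="mergesort").reset_index(drop=True)
    rng = np.random.default_rng([cfg.seed, group_index])
    perm = rng.permutation(len(sub))
    take = min(cfg.sample_n, len(sub))
    return sub.iloc[perm[:take]].reset_index(drop=True)


def gate_counts(metrics: pd.DataFrame, cfg: GateConfig) -> GateAssignment:
    """Sample ``cfg.sample_n`` tracklets per group and count gate labels.

    Raises ``ValueError`` naming the group when a group is smaller than the
    sample size, unless ``cfg.allow_short_groups`` (then the whole group is
    used and the shortfall recorded in the counts).
    """
    required = {"cell_id", "group", "start", "arrest", "directionality"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks column(s) {sorted(missing)}")
    samples = []
    for gi, g in enumerate(sorted(metrics["group"].unique())):
        sub = metrics[metrics["group"] == g]
        if len(sub) < cfg.sample_n and not cfg.allow_short_groups:
            raise ValueError(
                f"group {g!r} has {len(sub)} tracklets, fewer than sample_n={cfg.sample_n}"
            )
        samples.append(_sample_group(sub, cfg, gi))
    pooled = (pd.concat(samples, ignore_index=True) if samples
              else metrics.iloc[0:0].copy())
    sample = classify_table(pooled, cfg)
    counts = (
        sample.groupby("group")["gate"].value_counts().unstack(fill_value=0)
        .reindex(columns=list(GATE_LABELS), fill_value=0)
    )
    counts.columns.name = None
    return GateAssignment(sample=sample, counts=counts, config=cfg)


def gate_scatter_export(assignment: GateAssignment) -> pd.DataFrame:
    """Plot-ready table: one row per sampled tracklet with (A, Gamma, gate)."""
    cols = ["cell_id", "group", "start", "arrest", "directionality", "gate"]
    return assignment.sample[cols].copy()
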