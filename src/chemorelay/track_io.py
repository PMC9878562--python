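"""Reading, validation and regularization of time-lapse cell track tables.

Every downstream stage of the pipeline consumes one canonical structure, the
:class:`TrackTable`: a long-format table with one row per (cell, frame) in
canonical units (positions in micrometres, time in seconds, 0-based integer
frames).  Files are delimited text; a small dialect registry maps common
tracking-software export layouts onto the canonical columns.

2D data (no ``z`` column) are supported: positions are padded with ``z = 0``
internally and the dimensionality is remembered so round-trips are lossless.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("chemorelay")

__all__ = [
    "TrackTable",
    "Dialect",
    "DIALECTS",
    "TrackFormatError",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
    "regularize",
    "fill_gaps",
]

#: canonical column order for mandatory fields
MANDATORY_COLUMNS = ("cell_id", "group", "frame", "t", "x", "y")
POLARITY_COLUMNS = ("pol_x", "pol_y", "pol_z")

#: relative tolerance for "uniform sampling interval" checks
DT_RTOL = 1e-6


class TrackFormatError(ValueError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class TrackValidationError(ValueError):
    """A parsed table violates a TrackTable invariant."""


@dataclasses.dataclass(frozen=True)
class Dialect:
    """Column mapping and unit conventions of a delimited track export.

    Parameters
    ----------
    columns
        Mapping from canonical field name (``cell_id``, ``t``, ``x``, ``y``
        and optionally ``frame``, ``z``, ``group``, ``pol_x/y/z``) to the
        column name used in the file.
    delimiter
        Field separator.
    time_scale
        Multiplier converting file time values to seconds.
    position_scale
        Multiplier converting file positions to micrometres.
    frame_base
        Index of the first frame in the file (0 or 1).
    """

    name: str
    columns: Mapping[str, str]
    delimiter: str = ","
    time_scale: float = 1.0
    position_scale: float = 1.0
    frame_base: int = 0

    def __post_init__(self) -> None:
        missing = {"cell_id", "t", "x", "y"} - set(self.columns)
        if missing:
            raise ValueError(f"dialect {self.name!r} lacks mappings for {sorted(missing)}")


DIALECTS: dict[str, Dialect] = {
    "canonical": Dialect(
        name="canonical",
        columns={c: c for c in MANDATORY_COLUMNS + ("z",) + POLARITY_COLUMNS},
    ),
    # layout of a widespread commercial tracker export
    "imaris": Dialect(
        name="imaris",
        columns={
            "cell_id": "TrackID",
            "frame": "Time",          # frame index column
            "t": "Time [s]",
            "x": "Position X",
            "y": "Position Y",
            "z": "Position Z",
        },
        frame_base=1,
    ),
}


class TrackTable:
    """Validated long-format track table (the pipeline's common currency).

    Wraps a :class:`pandas.DataFrame` sorted by ``(cell_id, frame)`` with the
    canonical columns plus any extra annotation columns preserved opaquely.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        df["cell_id"] = df["cell_id"].astype(str)
        df["group"] = df["group"].astype(str)
        df["frame"] = df["frame"].astype(np.int64)
        for c in ("t", "x", "y"):
            df[c] = df[c].astype(float)
        if "z" in df.columns:
            if df["z"].isna().all():
                df = df.drop(columns=["z"])
            else:
                df["z"] = df["z"].astype(float)
        df = df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
        self.df = df
        if validate:
            self._validate()

    # -- invariants ---------------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        pos_cols = ["x", "y"] + (["z"] if "z" in df.columns else [])
        if not np.isfinite(df[pos_cols].to_numpy()).all():
            raise TrackValidationError("non-finite positions present")
        if not np.isfinite(df["t"].to_numpy()).all():
            raise TrackValidationError("non-finite times present")
        if df["frame"].min() < 0:
            raise TrackValidationError("negative frame index present")
        if "z" in df.columns:
            mixed = df.groupby("cell_id")["z"].apply(lambda s: s.isna().any() and s.notna().any())
            if mixed.any():
                bad = mixed[mixed].index[0]
                raise TrackValidationError(f"cell {bad!r} mixes 2D and 3D positions")
            if df["z"].isna().any():
                raise TrackValidationError("z present for some cells but absent for others")
        ngroups = df.groupby("cell_id")["group"].nunique()
        if (ngroups > 1).any():
            bad = ngroups[ngroups > 1].index[0]
            raise TrackValidationError(f"cell {bad!r} maps to more than one group")
        for cid, sub in df.groupby("cell_id", sort=False):
            fr = sub["frame"].to_numpy()
            if np.any(np.diff(fr) <= 0):
                raise TrackValidationError(f"duplicate or non-increasing frames for cell {cid!r}")
            tt = sub["t"].to_numpy()
            if np.any(np.diff(tt) <= 0):
                raise TrackValidationError(f"non-monotone time within cell {cid!r}")
        if self.has_polarity:
            pol = df[list(POLARITY_COLUMNS)].to_numpy(dtype=float)
            if not np.isfinite(pol).all():
                raise TrackValidationError("non-finite polarity vectors present")
            norms = np.linalg.norm(pol, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-3):
                raise TrackValidationError("polarity vectors must have unit norm")

    # -- accessors ----------------------------------------------------------

    @property
    def is_3d(self) -> bool:
        return "z" in self.df.columns

    @property
    def has_polarity(self) -> bool:
        return all(c in self.df.columns for c in POLARITY_COLUMNS)

    @property
    def cells(self) -> list[str]:
        return list(dict.fromkeys(self.df["cell_id"]))

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique())

    @property
    def n_cells(self) -> int:
        return self.df["cell_id"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def group_of(self, cell_id: str) -> str:
        sub = self.df.loc[self.df["cell_id"] == cell_id, "group"]
        if sub.empty:
            raise KeyError(cell_id)
        return sub.iloc[0]

    def positions(self, cell_id: str) -> np.ndarray:
        """(n, 3) positions of one cell; z = 0 in 2D mode."""
        sub = self.df[self.df["cell_id"] == cell_id]
        if sub.empty:
            raise KeyError(cell_id)
        xyz = np.zeros((len(sub), 3))
        xyz[:, 0] = sub["x"].to_numpy()
        xyz[:, 1] = sub["y"].to_numpy()
        if self.is_3d:
            xyz[:, 2] = sub["z"].to_numpy()
        return xyz

    def times(self, cell_id: str) -> np.ndarray:
        sub = self.df[self.df["cell_id"] == cell_id]
        if sub.empty:
            raise KeyError(cell_id)
        return sub["t"].to_numpy()

    def polarity(self, cell_id: str) -> np.ndarray | None:
        if not self.has_polarity:
            return None
        sub = self.df[self.df["cell_id"] == cell_id]
        return sub[list(POLARITY_COLUMNS)].to_numpy(dtype=float)

    def dt(self, cell_id: str | None = None) -> float:
        """Uniform inter-frame interval (seconds).

        With ``cell_id=None`` the table-wide interval is returned; raises
        :class:`TrackValidationError` if sampling is not uniform to within
        relative tolerance — run :func:`regularize` first.
        """
        if cell_id is not None:
            diffs = np.diff(self.times(cell_id))
        else:
            diffs = np.concatenate(
                [np.diff(sub["t"].to_numpy()) for _, sub in self.df.groupby("cell_id", sort=False)
                 if len(sub) > 1]
            )
        if diffs.size == 0:
            raise TrackValidationError("no inter-frame intervals (all tracks single-frame)")
        d0 = float(np.median(diffs))
        if np.any(np.abs(diffs - d0) > DT_RTOL * d0):
            raise TrackValidationError("sampling interval is not uniform; regularize first")
        return d0

    def equals(self, other: "TrackTable", atol: float = 0.0) -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind in "fc":
                if not np.allclose(a[c].to_numpy(), b[c].to_numpy(), atol=atol, rtol=0):
                    return False
            elif not (a[c].to_numpy() == b[c].to_numpy()).all():
                return False
        return True


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _resolve_dialect(dialect: str | Dialect) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise TrackFormatError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        ) from None


def read_tracks(
    path,
    dialect: str | Dialect = "canonical",
    group_map: Mapping[str, str] | None = None,
    default_group: str | None = None,
) -> TrackTable:
    """Read a delimited track file into a validated :class:`TrackTable`.

    Parameters
    ----------
    path
        Delimited text file.
    dialect
        Registered dialect name or a :class:`Dialect` describing the layout.
    group_map
        Optional mapping ``cell_id -> group`` used when the file has no group
        column (cell ids are compared as strings).
    default_group
        Group label assigned to cells not covered by the file or
        ``group_map``.

    Unknown columns are preserved as opaque annotations.
    """
    dia = _resolve_dialect(dialect)
    raw = pd.read_csv(path, sep=dia.delimiter)
    rename = {}
    for canon, col in dia.columns.items():
        if col in raw.columns:
            rename[col] = canon
        elif canon in ("cell_id", "t", "x", "y"):
            raise TrackFormatError(
                f"missing mandatory column {col!r} (field {canon!r}) in {path}"
            )
    df = raw.rename(columns=rename)
    df["cell_id"] = df["cell_id"].astype(str)

    if "frame" not in df.columns:
        df = df.sort_values(["cell_id", "t"], kind="mergesort")
        df["frame"] = df.groupby("cell_id").cumcount()
    else:
        df["frame"] = pd.to_numeric(df["frame"]) - dia.frame_base
    dup = df.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        bad = df.loc[dup, "cell_id"].iloc[0]
        raise TrackValidationError(f"duplicated (cell_id, frame) row for cell {bad!r}")

    df["t"] = pd.to_numeric(df["t"]) * dia.time_scale
    for c in ("x", "y", "z"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c]) * dia.position_scale

    if "group" not in df.columns:
        if group_map is not None:
            df["group"] = df["cell_id"].map(lambda cid: group_map.get(cid, default_group))
            if df["group"].isna().any():
                bad = df.loc[df["group"].isna(), "cell_id"].iloc[0]
                raise TrackFormatError(f"no group for cell {bad!r} and no default_group")
        elif default_group is not None:
            df["group"] = default_group
        else:
            raise TrackFormatError(
                "file has no group column; provide group_map or default_group"
            )

    order = [c for c in MANDATORY_COLUMNS + ("z",) + POLARITY_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in order]
    return TrackTable(df[order + extra])


def write_tracks(table: TrackTable, path) -> None:
    """Write a table in the canonical dialect, losslessly re-readable."""
    df = table.df.copy()
    # full float precision so round-trips are exact at the printed precision
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# gap filling and resampling
# ---------------------------------------------------------------------------

def fill_gaps(table: TrackTable, max_gap: int = 2) -> TrackTable:
    """Close small frame gaps by linear interpolation, split at large ones.

    Gaps of at most ``max_gap`` missing frames are filled assuming the cell's
    modal inter-frame interval; larger gaps split the track into separately
    identified segments suffixed ``#0``, ``#1``, ...  Tracklet metrics assume
    uniform sampling, so this runs before :func:`regularize` on real exports.
    """
    out = []
    pos_cols = ["x", "y"] + (["z"] if table.is_3d else [])
    for cid, sub in table.df.groupby("cell_id", sort=False):
        fr = sub["frame"].to_numpy()
        gaps = np.diff(fr) - 1
        split_at = np.flatnonzero(gaps > max_gap) + 1
        segments = np.split(np.arange(len(fr)), split_at)
        nseg = len(segments)
        for si, seg in enumerate(segments):
            part = sub.iloc[seg]
            sid = cid if nseg == 1 else f"{cid}#{si}"
            fr_s = part["frame"].to_numpy()
            full = np.arange(fr_s[0], fr_s[-1] + 1)
            if len(full) == len(fr_s):
                part = part.assign(cell_id=sid)
                out.append(part)
                continue
            logger.info("fill_gaps: interpolating %d frame(s) inside cell %s",
                        len(full) - len(fr_s), sid)
            filled = pd.DataFrame({"cell_id": sid, "group": part["group"].iloc[0],
                                   "frame": full})
            for c in ["t"] + pos_cols:
                filled[c] = np.interp(full, fr_s, part[c].to_numpy())
            out.append(filled)
        if nseg > 1:
            logger.info("fill_gaps: split cell %s into %d segments", cid, nseg)
    df = pd.concat(out, ignore_index=True)
    return TrackTable(df)


def regularize(table: TrackTable, dt_target: float) -> TrackTable:
    """Resample every track to a uniform grid of ``dt_target`` seconds.

    Positions (and polarity, renormalized) are linearly interpolated between
    flanking frames; each cell keeps its own start time and is never
    extrapolated beyond its last observed frame.  Cells left with fewer than
    2 frames are dropped and logged.  Down-sampling only: ``dt_target`` must
    be at least the native interval.
    """
    if dt_target <= 0:
        raise ValueError("dt_target must be positive")
    df = table.df
    native = np.concatenate(
        [np.diff(sub["t"].to_numpy()) for _, sub in df.groupby("cell_id", sort=False)
         if len(sub) > 1]
    )
    if native.size == 0:
        raise TrackValidationError("nothing to regularize: all tracks single-frame")
    dt_min = float(native.min())
    if dt_target < dt_min * (1 - DT_RTOL):
        raise ValueError(
            f"dt_target={dt_target} s is below the native interval {dt_min} s; "
            "upsampling is not supported"
        )
    # identity shortcut: already uniform on the target grid
    if np.all(np.abs(native - dt_target) <= DT_RTOL * dt_target):
        return TrackTable(df.copy(), validate=False)

    pos_cols = ["x", "y"] + (["z"] if table.is_3d else [])
    pol_cols = list(POLARITY_COLUMNS) if table.has_polarity else []
    out = []
    dropped = 0
    for cid, sub in df.groupby("cell_id", sort=False):
        tt = sub["t"].to_numpy()
        n_new = int(np.floor((tt[-1] - tt[0]) / dt_target + DT_RTOL)) + 1
        if n_new < 2:
            dropped += 1
            continue
        grid = tt[0] + dt_target * np.arange(n_new)
        new = pd.DataFrame({"cell_id": cid, "group": sub["group"].iloc[0],
                            "frame": np.arange(n_new), "t": grid})
        for c in pos_cols:
            new[c] = np.interp(grid, tt, sub[c].to_numpy())
        if pol_cols:
            pol = np.column_stack([np.interp(grid, tt, sub[c].to_numpy()) for c in pol_cols])
            norms = np.linalg.norm(pol, axis=1)
            # fall back to the nearest observed vector where interpolation cancels
            degenerate = norms < 1e-9
            if degenerate.any():
                idx = np.searchsorted(tt, grid[degenerate])
                idx = np.clip(idx, 0, len(tt) - 1)
                pol[degenerate] = sub[pol_cols].to_numpy()[idx]
                norms = np.linalg.norm(pol, axis=1)
            pol /= norms[:, None]
            for j, c in enumerate(pol_cols):
                new[c] = pol[:, j]
        out.append(new)
    if dropped:
        logger.info("regularize: dropped %d cell(s) shorter than 2 frames on the new grid",
                    dropped)
    if not out:
        raise TrackValidationError("regularize dropped every track")
    return TrackTable(pd.concat(out, ignore_index=True))
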