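"""Reading, writing, validating, and filtering 3D track and centroid tables.

Two table dialects are supported:

``generic``
    The package's own strict format: literal headers
    ``track_id,t_seconds,x_um,y_um,z_um[,category]``, one row per frame.

``imaris_position``
    The permissive "Position" export of the Imaris tracking software: columns
    ``Position X``/``Position Y``/``Position Z`` (μm), ``Time`` and
    ``TrackID``, preceded by a fixed number of preamble lines.  ``Time`` may
    hold a frame index (the common case, converted to seconds using a nominal
    frame interval) or seconds directly.

All coordinates are micrometres and all internal times are seconds; motility
statistics downstream report speeds in μm/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gcsearch.errors import FormatError, ValidationError

#: Nominal imaging frame interval (s) used when a dialect stores frame indices.
DEFAULT_FRAME_INTERVAL = 30.0

#: Relative tolerance on frame-spacing uniformity within a track.
_SPACING_RTOL = 1e-6

GENERIC_COLUMNS = ["track_id", "t_seconds", "x_um", "y_um", "z_um"]
_IMARIS_PREAMBLE_LINES = 2
_IMARIS_COLUMNS = {
    "x": "Position X",
    "y": "Position Y",
    "z": "Position Z",
    "time": "Time",
    "track": "TrackID",
}


@dataclass
class Track:
    """One object's time-ordered 3D positions at uniform frame spacing.

    Parameters
    ----------
    track_id
        Opaque identifier (kept as a string internally).
    times
        Frame times in seconds, strictly increasing, uniformly spaced.
    positions
        ``(n_frames, 3)`` array of x/y/z coordinates in μm.
    category
        Free label, e.g. ``"GC B cell"``, ``"TBM"``, ``"fragment"``.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    category: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 3):
            raise ValidationError(
                f"track {self.track_id!r}: times must be 1D and positions (n, 3); "
                f"got {self.times.shape} and {self.positions.shape}"
            )
        if self.times.size < 2:
            raise ValidationError(f"track {self.track_id!r}: needs at least 2 frames")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.positions)):
            raise ValidationError(f"track {self.track_id!r}: non-finite time or coordinate")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValidationError(f"track {self.track_id!r}: time not strictly increasing")
        dt0 = dts[0]
        if not np.allclose(dts, dt0, rtol=_SPACING_RTOL, atol=1e-9):
            raise ValidationError(
                f"track {self.track_id!r}: non-uniform frame spacing ({dts.min():g}–{dts.max():g} s)"
            )

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def frame_interval(self) -> float:
        """Frame spacing in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Elapsed time from first to last frame, seconds."""
        return float(self.times[-1] - self.times[0])


@dataclass
class TrackSet:
    """A collection of tracks sharing one nominal frame interval."""

    tracks: list[Track]
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate track ids: {dupes}")
        for t in self.tracks:
            if not math.isclose(t.frame_interval, self.frame_interval, rel_tol=1e-6):
                raise ValidationError(
                    f"track {t.track_id!r} has frame interval {t.frame_interval:g} s, "
                    f"set expects {self.frame_interval:g} s"
                )

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass
class PointSet3D:
    """Unordered 3D centroids (e.g. macrophage positions) in μm."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValidationError("PointSet3D needs an (n>=1, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("PointSet3D contains non-finite coordinates")

    def __len__(self) -> int:
        return self.points.shape[0]


def _read_table(path: Path, skiprows: int = 0) -> pd.DataFrame:
    # sep=None sniffs comma vs tab; engine="python" is required for sniffing
    return pd.read_csv(path, sep=None, engine="python", skiprows=skiprows)


def _infer_frame_interval(df: pd.DataFrame, id_col: str, t_col: str) -> float:
    diffs = df.groupby(id_col, sort=False)[t_col].diff().dropna().to_numpy()
    if diffs.size == 0:
        return DEFAULT_FRAME_INTERVAL
    vals, counts = np.unique(diffs, return_counts=True)
    return float(vals[np.argmax(counts)])


def read_tracks(
    path: str | Path,
    dialect: str = "generic",
    *,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    time_in_seconds: bool | None = None,
) -> TrackSet:
    """Read a track table into a :class:`TrackSet`.

    Rows are grouped by track id and sorted by time, so input row order is
    irrelevant.  The set's ``frame_interval`` is the modal within-track time
    difference.

    Parameters
    ----------
    dialect
        ``"generic"`` or ``"imaris_position"`` (see module docstring).
    frame_interval
        Seconds per frame, used to convert frame indices to seconds when the
        dialect stores frame indices.
    time_in_seconds
        Override the dialect's time-unit convention: the exporting software
        does not record whether ``Time`` is a frame index or seconds.  Default
        is ``False`` (frame index) for ``imaris_position`` and ``True`` for
        ``generic``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "generic":
        df = _read_table(path)
        missing = [c for c in GENERIC_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing required column(s) {missing}")
        id_col, t_col = "track_id", "t_seconds"
        x_col, y_col, z_col = "x_um", "y_um", "z_um"
        cat_col = "category" if "category" in df.columns else None
        in_seconds = True if time_in_seconds is None else time_in_seconds
    elif dialect == "imaris_position":
        df = _read_table(path, skiprows=_IMARIS_PREAMBLE_LINES)
        missing = [c for c in _IMARIS_COLUMNS.values() if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing required column(s) {missing}")
        id_col, t_col = _IMARIS_COLUMNS["track"], _IMARIS_COLUMNS["time"]
        x_col, y_col, z_col = (_IMARIS_COLUMNS[k] for k in ("x", "y", "z"))
        cat_col = "Category" if "Category" in df.columns else None
        in_seconds = False if time_in_seconds is None else time_in_seconds
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not in_seconds:
        df = df.copy()
        df[t_col] = df[t_col].astype(float) * frame_interval

    df = df.sort_values([id_col, t_col], kind="mergesort")
    tracks: list[Track] = []
    for tid, grp in df.groupby(id_col, sort=False):
        times = grp[t_col].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"track {tid!r}: duplicate or non-monotone time values")
        pos = grp[[x_col, y_col, z_col]].to_numpy(dtype=float)
        category = str(grp[cat_col].iloc[0]) if cat_col else ""
        tracks.append(Track(str(tid), times, pos, category=category))

    fi = _infer_frame_interval(df, id_col, t_col) if tracks else DEFAULT_FRAME_INTERVAL
    return TrackSet(tracks, frame_interval=fi, provenance=str(path))


def to_dataframe(ts: TrackSet) -> pd.DataFrame:
    """Flatten a TrackSet into a generic-dialect DataFrame (sorted rows)."""
    frames = []
    for tr in sorted(ts.tracks, key=lambda t: t.track_id):
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "t_seconds": tr.times,
                    "x_um": tr.positions[:, 0],
                    "y_um": tr.positions[:, 1],
                    "z_um": tr.positions[:, 2],
                    "category": tr.category,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=GENERIC_COLUMNS + ["category"])
    return pd.concat(frames, ignore_index=True)


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    """Write a TrackSet in the generic dialect.

    Rows are ordered by (track_id, time) and coordinates are written with
    enough digits that a read/write round trip preserves them to at least six
    significant figures.
    """
    df = to_dataframe(ts)
    df.to_csv(path, index=False, float_format="%.10g")


def filter_tracks(ts: TrackSet, min_duration: float = 150.0) -> TrackSet:
    """Drop short-lived tracks: keep those with duration strictly > ``min_duration`` s.

    The default of 150 s (five 30-s steps) removes short-lived/noisy tracks;
    a 4-frame track spanning 90 s is dropped, a 7-frame track spanning 180 s
    is kept.  Idempotent; preserves track order.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    kept = [t for t in ts.tracks if t.duration > min_duration]
    return TrackSet(kept, frame_interval=ts.frame_interval, provenance=ts.provenance)


def read_points(path: str | Path, dialect: str = "generic") -> PointSet3D:
    """Read a 3D centroid table (columns ``x_um,y_um,z_um`` or Imaris
    ``Position X/Y/Z``)."""
    path = Path(path)
    if dialect == "generic":
        df = _read_table(path)
        cols = ["x_um", "y_um", "z_um"]
    elif dialect == "imaris_position":
        df = _read_table(path, skiprows=_IMARIS_PREAMBLE_LINES)
        cols = [_IMARIS_COLUMNS[k] for k in ("x", "y", "z")]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    return PointSet3D(df[cols].to_numpy(dtype=float), label=str(path))


def write_points(ps: PointSet3D, path: str | Path) -> None:
    df = pd.DataFrame(ps.points, columns=["x_um", "y_um", "z_um"])
    df.to_csv(path, index=False, float_format="%.10g")
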