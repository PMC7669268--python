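"""Track-table and frame I/O plus track-quality filtering.

Tracks are held in the common long format of tracking-software position
exports: a pandas DataFrame with columns ``track_id, t, x, y, z`` where
``t`` is in minutes and positions in µm.  Recorded simulation frames (one
xy point set per time) travel as :class:`Frame` objects and are stored as
long-format ``t, x, y`` tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRACK_COLUMNS",
    "Frame",
    "TrackFilterConfig",
    "validate_tracks",
    "read_tracks",
    "write_tracks",
    "filter_tracks",
    "track_sampling_interval",
    "write_frames",
    "read_frames",
]

TRACK_COLUMNS = ("track_id", "t", "x", "y", "z")

#: fixed float formatting for frame output, so outputs are bit-stable
_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class Frame:
    """xy positions of cells recorded in one imaging/recording plane.

    Attributes
    ----------
    t : float
        Time of the frame, minutes.
    positions : ndarray, shape (n, 2)
        xy positions in µm.
    """

    t: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        if pos.shape[1] != 2:
            raise ValueError("frame positions must be (n, 2) xy points")
        if not np.all(np.isfinite(pos)):
            raise ValueError("frame positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_cells(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class TrackFilterConfig:
    """Track-quality filter: drop tracks of insufficient duration.

    ``min_duration`` (minutes, default 10) is inclusive — a track lasting
    exactly ``min_duration`` is kept.
    """

    min_duration: float = 10.0

    def __post_init__(self) -> None:
        if self.min_duration < 0:
            raise ValueError("min_duration must be >= 0")


class TrackValidationError(ValueError):
    """A track table violates the schema or monotone-time requirements."""


def validate_tracks(tracks: pd.DataFrame, check_interval: bool = True) -> pd.DataFrame:
    """Validate and normalise a track table.

    Returns a copy sorted by (track_id, t) with exactly the canonical
    columns.  Raises :class:`TrackValidationError` on schema problems,
    non-finite positions, duplicated or non-increasing time stamps, or
    (when ``check_interval``) a per-track sampling interval that varies by
    more than 1%.
    """
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise TrackValidationError(f"missing track columns: {missing}")
    out = tracks.loc[:, list(TRACK_COLUMNS)].copy()
    for c in ("t", "x", "y", "z"):
        out[c] = pd.to_numeric(out[c], errors="raise")
    if not np.all(np.isfinite(out[["t", "x", "y", "z"]].to_numpy())):
        raise TrackValidationError("non-finite values in track table")
    out = out.sort_values(["track_id", "t"], kind="mergesort").reset_index(drop=True)
    for tid, grp in out.groupby("track_id", sort=False):
        dt = np.diff(grp["t"].to_numpy())
        if len(dt) and np.any(dt <= 0):
            raise TrackValidationError(f"non-increasing or duplicated time in track {tid!r}")
        if check_interval and len(dt) > 1:
            if (dt.max() - dt.min()) > 0.01 * dt.mean():
                raise TrackValidationError(f"irregular sampling interval in track {tid!r}")
    return out


def track_sampling_interval(tracks: pd.DataFrame) -> float:
    """Common sampling interval of a validated track table, minutes."""
    dts = []
    for _, grp in tracks.groupby("track_id", sort=False):
        d = np.diff(grp["t"].to_numpy())
        if len(d):
            dts.append(np.median(d))
    if not dts:
        raise ValueError("no multi-point tracks in table")
    dt = float(np.median(dts))
    if any(abs(x - dt) > 0.01 * dt for x in dts):
        raise TrackValidationError("tracks do not share a common sampling interval")
    return dt


def read_tracks(path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited track table (CSV by default, TSV accepted).

    Column names are resolved case-insensitively; extra columns are
    dropped.  The result is validated and sorted by (track_id, t).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    rename = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for want in TRACK_COLUMNS:
        if want in lower:
            rename[lower[want]] = want
    df = df.rename(columns=rename)
    return validate_tracks(df)


def write_tracks(tracks: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a track table as delimited text with header."""
    validate_tracks(tracks).to_csv(path, sep=sep, index=False)


def filter_tracks(tracks: pd.DataFrame, cfg: TrackFilterConfig = TrackFilterConfig()) -> pd.DataFrame:
    """Drop tracks whose duration (last t − first t) is below the threshold.

    A pure subset: surviving rows are untouched.  Tracks of duration
    exactly ``min_duration`` are kept.
    """
    if len(tracks) == 0:
        return tracks.copy()
    dur = tracks.groupby("track_id")["t"].agg(lambda s: s.max() - s.min())
    keep = dur[dur >= cfg.min_duration].index
    return tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)


def write_frames(frames, path, sep: str = ",") -> None:
    """Write recorded frames as a long-format (t, x, y) table.

    Floats are formatted at 6 significant digits so output is bit-stable.
    """
    frames = list(frames)
    ts = [f.t for f in frames]
    if ts != sorted(ts):
        raise ValueError("frames must be time-sorted")
    rows = []
    for f in frames:
        for x, y in f.positions:
            rows.append((f.t, x, y))
    df = pd.DataFrame(rows, columns=["t", "x", "y"])
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_frames(path, sep: str = ",") -> list[Frame]:
    """Read frames written by :func:`write_frames`."""
    df = pd.read_csv(path, sep=sep)
    for c in ("t", "x", "y"):
        if c not in df.columns:
            raise TrackValidationError(f"missing frame column {c!r}")
    frames = []
    for t, grp in df.groupby("t", sort=True):
        frames.append(Frame(t=float(t), positions=grp[["x", "y"]].to_numpy(dtype=float)))
    return frames
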