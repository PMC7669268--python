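"""Quantification of swarming, chemotaxis and infiltration.

The central statistic is the swarming index M, a per-frame summary of
where cells sit relative to the tumouroid, anchored at three points:
−1 when every cell sits on the well perimeter, 0 in expectation when
cells are uniformly distributed outside the tumouroid, and +1 when every
cell has infiltrated.  Cells inside the tumouroid score +1; a cell
outside at in-plane distance rho from the arena centre scores 1 − 2u with

    u = (rho² − R_t²) / (R_w² − R_t²)

the area-fraction coordinate of the annulus between tumouroid radius R_t
and well radius R_w (u is uniform on [0, 1] for spatially uniform cells,
so the per-cell score is uniform on [−1, 1] and averages to 0).

Also here: the forward migration index (FMI — net displacement projected
on a toward-target unit vector over net displacement magnitude, i.e. the
cosine of the angle to the target), per-track displacement/speed
summaries, infiltrated fraction and depth, radial density kymographs
(smoothed derivative of the cumulative cell count over distance from the
tumouroid interface), a binned instantaneous-FMI kymograph, and the
transwell transmigration and cytotoxicity indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .geometry import ArenaConfig, inside_tumouroid, radial_distance
from .tracks import Frame

__all__ = [
    "swarming_index",
    "swarming_series",
    "fmi",
    "track_summary",
    "TrackSummary",
    "infiltration_stats",
    "InfiltrationStats",
    "cumulative_radial_counts",
    "density_kymograph",
    "KymographGrid",
    "instantaneous_fmi_kymograph",
    "transmigration_index",
    "cytotoxicity_index",
]


# ---------------------------------------------------------------------------
# swarming index


def swarming_index(frame: Frame, arena: ArenaConfig) -> float:
    """Swarming index M of one frame, in [−1, 1].

    Raises on an empty frame or on cells outside the well.
    """
    if frame.n_cells == 0:
        raise ValueError("swarming index is undefined for an empty frame")
    rho = np.hypot(
        frame.positions[:, 0] - arena.centre[0],
        frame.positions[:, 1] - arena.centre[1],
    )
    rw, rt = arena.well_radius, arena.tumouroid_radius
    # tolerate rounding from fixed-precision frame storage (6 significant
    # digits), which can push a wall-hugging cell ~0.01 µm past the wall
    if np.any(rho > rw * (1 + 1e-4)):
        raise ValueError("frame contains cells outside the well")
    u = np.clip((rho**2 - rt**2) / (rw**2 - rt**2), None, 1.0)
    score = np.where(rho < rt, 1.0, 1.0 - 2.0 * u)
    return float(score.mean())


def swarming_series(frames, arena: ArenaConfig) -> pd.DataFrame:
    """Swarming index per frame; columns ``t`` (min) and ``M``.

    Empty frames yield NaN rather than an error so long series survive
    sparse early time points.
    """
    rows = []
    for f in frames:
        m = swarming_index(f, arena) if f.n_cells else np.nan
        rows.append((f.t, m))
    return pd.DataFrame(rows, columns=["t", "M"])


# ---------------------------------------------------------------------------
# forward migration index and track summaries


def _unit(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.shape[0] not in (2, 3):
        raise ValueError("target direction must be a 2- or 3-vector")
    if u.shape[0] == 2:
        u = np.array([u[0], u[1], 0.0])
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("target direction must be nonzero")
    return u / norm


def fmi(positions, target_direction) -> float:
    """Forward migration index of one track toward ``target_direction``.

    positions : (n, 2 or 3) array of ordered track positions.
    Raises on fewer than two points or zero net displacement.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(pos) < 2:
        raise ValueError("FMI needs at least two track points")
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(len(pos))])
    net = pos[-1] - pos[0]
    d = np.linalg.norm(net)
    if d == 0:
        raise ValueError("FMI undefined for zero net displacement")
    return float(net @ _unit(target_direction) / d)


@dataclass(frozen=True)
class TrackSummary:
    """Per-track motility statistics plus the tracks excluded and why."""

    stats: pd.DataFrame          # track_id, displacement, axis_displacement, fmi, mean_speed, duration
    excluded: pd.DataFrame       # track_id, reason


def track_summary(tracks: pd.DataFrame, target_direction) -> TrackSummary:
    """Displacement, projected displacement, FMI, mean speed and duration
    per track.

    displacement is the straight first-to-last distance; mean_speed is
    total path length over duration.  Single-point tracks and tracks with
    zero net displacement are excluded and reported, not silently
    dropped.
    """
    u = _unit(target_direction)
    rows, excluded = [], []
    for tid, grp in tracks.groupby("track_id", sort=False):
        pos = grp[["x", "y", "z"]].to_numpy()
        t = grp["t"].to_numpy()
        if len(pos) < 2:
            excluded.append((tid, "single point"))
            continue
        net = pos[-1] - pos[0]
        d = float(np.linalg.norm(net))
        duration = float(t[-1] - t[0])
        path = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
        if d == 0:
            excluded.append((tid, "zero net displacement"))
            continue
        rows.append(
            (tid, d, float(net @ u), float(net @ u / d), path / duration, duration)
        )
    return TrackSummary(
        stats=pd.DataFrame(
            rows,
            columns=["track_id", "displacement", "axis_displacement", "fmi", "mean_speed", "duration"],
        ),
        excluded=pd.DataFrame(excluded, columns=["track_id", "reason"]),
    )


# ---------------------------------------------------------------------------
# infiltration


@dataclass(frozen=True)
class InfiltrationStats:
    """Fraction of cells inside the tumouroid and their depths (µm)."""

    fraction_infiltrated: float
    depths: np.ndarray
    mean_depth: float            # NaN when nothing infiltrated


def infiltration_stats(frame: Frame, arena: ArenaConfig) -> InfiltrationStats:
    """Infiltrated fraction and per-cell infiltration depth of one frame.

    Depth is the shortest distance from the tumouroid edge, i.e.
    R_t − rho for an infiltrated cell.
    """
    if frame.n_cells == 0:
        return InfiltrationStats(0.0, np.empty(0), float("nan"))
    d = radial_distance(frame.positions, arena)
    depths = -d[d < 0]
    frac = len(depths) / frame.n_cells
    mean_depth = float(depths.mean()) if len(depths) else float("nan")
    return InfiltrationStats(float(frac), depths, mean_depth)


# ---------------------------------------------------------------------------
# density kymograph


@dataclass(frozen=True)
class KymographGrid:
    """Cell density over (distance from tumouroid edge, time).

    ``density`` is per unit area (cells/µm², the r-derivative of the
    cumulative count divided by the circumference at that radius);
    ``density_per_r`` is the raw r-derivative (cells/µm).  ``counts``
    holds the exact pre-smoothing cumulative counts N(r) per frame.
    """

    r: np.ndarray                 # µm from tumouroid edge
    t: np.ndarray                 # min
    density: np.ndarray           # (len(t), len(r)) cells/µm²
    density_per_r: np.ndarray     # (len(t), len(r)) cells/µm
    counts: np.ndarray            # (len(t), len(r)) cumulative counts
    n_negative_clipped: int

    def to_dataframe(self) -> pd.DataFrame:
        tt, rr = np.meshgrid(self.t, self.r, indexing="ij")
        return pd.DataFrame(
            {
                "t": tt.ravel(),
                "r": rr.ravel(),
                "density": self.density.ravel(),
                "density_per_r": self.density_per_r.ravel(),
                "cumulative_count": self.counts.ravel(),
            }
        )


def cumulative_radial_counts(frame: Frame, arena: ArenaConfig, r_grid: np.ndarray) -> np.ndarray:
    """N(r): number of cells outside the tumouroid within radial distance
    r of its interface, for each r in ``r_grid``."""
    d = radial_distance(frame.positions, arena) if frame.n_cells else np.empty(0)
    d = d[d >= 0]
    return np.searchsorted(np.sort(d), r_grid, side="right").astype(float)


def density_kymograph(
    frames,
    arena: ArenaConfig,
    r_grid: np.ndarray | None = None,
    smoothing: float | None = None,
) -> KymographGrid:
    """Radial cell-density kymograph over all frames.

    Per frame the cumulative count N(r) of cells within radial distance r
    of the tumouroid interface is computed exactly, smoothed over r with
    a cubic penalised spline (penalty chosen by generalised
    cross-validation unless ``smoothing`` is given), and differentiated
    with respect to r.  Dividing the derivative by the circumference
    2π(R_t + r) converts it to a per-area density.  Negative smoothed
    densities are clipped to zero and counted.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("density_kymograph needs at least one frame")
    if r_grid is None:
        r_grid = np.linspace(0.0, arena.well_radius - arena.tumouroid_radius, 64)
    r_grid = np.asarray(r_grid, dtype=float)
    if len(r_grid) < 4 or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be increasing with at least 4 points")

    t = np.array([f.t for f in frames])
    counts = np.vstack([cumulative_radial_counts(f, arena, r_grid) for f in frames])
    dens_r = np.empty_like(counts)
    clipped = 0
    for i in range(len(frames)):
        if counts[i, -1] == 0:          # empty frame: flat zero density
            dens_r[i] = 0.0
            continue
        spline = make_smoothing_spline(r_grid, counts[i], lam=smoothing)
        deriv = spline.derivative()(r_grid)
        clipped += int(np.count_nonzero(deriv < 0))
        dens_r[i] = np.clip(deriv, 0.0, None)
    circumference = 2.0 * np.pi * (arena.tumouroid_radius + r_grid)
    density = dens_r / circumference[None, :]
    return KymographGrid(
        r=r_grid, t=t, density=density, density_per_r=dens_r,
        counts=counts, n_negative_clipped=clipped,
    )


# ---------------------------------------------------------------------------
# instantaneous FMI kymograph


def instantaneous_fmi_kymograph(
    tracks: pd.DataFrame,
    arena: ArenaConfig,
    r_bins: np.ndarray,
    t_bins: np.ndarray,
) -> pd.DataFrame:
    """Mean per-step FMI binned over (distance from tumouroid edge, time).

    Each step displacement is scored against the local toward-tumouroid
    direction (the inward radial direction at the step's start point);
    the score is the cosine of the angle between them.  Bins with no
    observations hold NaN — distinguishable from a genuine mean of zero.
    Returns a DataFrame indexed by r-bin left edges with t-bin left edges
    as columns.
    """
    r_bins = np.asarray(r_bins, dtype=float)
    t_bins = np.asarray(t_bins, dtype=float)
    starts, vecs, times = [], [], []
    for _, grp in tracks.groupby("track_id", sort=False):
        pos = grp[["x", "y", "z"]].to_numpy()
        t = grp["t"].to_numpy()
        if len(pos) < 2:
            continue
        starts.append(pos[:-1])
        vecs.append(np.diff(pos, axis=0))
        times.append(t[:-1])
    if not starts:
        raise ValueError("no multi-point tracks")
    starts = np.concatenate(starts)
    vecs = np.concatenate(vecs)
    times = np.concatenate(times)

    toward = np.column_stack(
        [arena.centre[0] - starts[:, 0], arena.centre[1] - starts[:, 1]]
    )
    toward_norm = np.linalg.norm(toward, axis=1)
    speed = np.linalg.norm(vecs, axis=1)
    ok = (toward_norm > 0) & (speed > 0)
    score = (vecs[ok, 0] * toward[ok, 0] + vecs[ok, 1] * toward[ok, 1]) / (
        toward_norm[ok] * speed[ok]
    )
    rdist = radial_distance(starts[ok], arena)

    sums, _, _ = np.histogram2d(rdist, times[ok], bins=[r_bins, t_bins], weights=score)
    ns, _, _ = np.histogram2d(rdist, times[ok], bins=[r_bins, t_bins])
    with np.errstate(invalid="ignore"):
        mean = np.where(ns > 0, sums / ns, np.nan)
    return pd.DataFrame(mean, index=r_bins[:-1], columns=t_bins[:-1])


# ---------------------------------------------------------------------------
# plate-assay indices


def transmigration_index(n_sample: float, n_control: float) -> float:
    """Cells transmigrated toward the sample over those toward control medium."""
    if n_control <= 0:
        raise ValueError("transmigration index undefined for zero control count")
    if n_sample < 0:
        raise ValueError("cell counts must be >= 0")
    return n_sample / n_control


def cytotoxicity_index(cog_0h: float, noncog_0h: float, cog_2h: float, noncog_2h: float) -> float:
    """Percent loss of cognate targets relative to non-cognate bystanders:
    [1 − (cog_2h/noncog_2h) / (cog_0h/noncog_0h)] × 100."""
    if noncog_0h <= 0 or noncog_2h <= 0 or cog_0h <= 0:
        raise ValueError("cytotoxicity index requires positive reference counts")
    return (1.0 - (cog_2h / noncog_2h) / (cog_0h / noncog_0h)) * 100.0
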