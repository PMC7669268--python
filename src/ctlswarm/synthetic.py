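"""Synthetic 3D motility tracks: persistent random walks with optional drift.

The bootstrap simulator replays blocks of real CTL tracks; this module
generates stand-in pools with the same statistical structure so the whole
pipeline is testable without imaging data.  Each step direction is a
normalised convex mix of the previous direction (weight ``persistence``),
a fixed drift direction (weight ``drift_weight``) and an isotropic random
unit vector (the remaining weight); step lengths are positive draws from a
truncated normal around ``speed_mean * dt``.

Two preset parameter sets mirror the two experimental source pools the
simulator samples from: an undirected pool (random migration, no target)
and a chemotactic pool (tracks biased toward a fixed reference direction,
standing in for CTLs migrating toward a cognate tumouroid located in the
−x direction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WalkParams",
    "generate_walks",
    "undirected_walk_params",
    "chemotactic_walk_params",
    "REFERENCE_DIRECTION",
]

#: conventional toward-target direction of the chemotactic source pool
#: (the tumouroid sits toward −x in the source experiments)
REFERENCE_DIRECTION = (-1.0, 0.0)

# Field-typical effector T-cell motility in 3D collagen; chosen once as the
# package's study conditions (see docs/methods.md).
_SPEED_MEAN = 4.0     # µm/min
_SPEED_SD = 1.5       # µm/min
_PERSISTENCE = 0.4
_CHEMOTACTIC_DRIFT = 0.4


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the persistent-random-walk generator.

    ``persistence`` and ``drift_weight`` are convex mixing weights in
    [0, 1] with ``persistence + drift_weight <= 1``; the remainder weights
    an isotropic random unit vector.  ``dt`` defaults to 1/3 min (20 s).
    """

    n_tracks: int
    duration: float            # min
    speed_mean: float          # µm/min
    speed_sd: float            # µm/min
    dt: float = 1.0 / 3.0      # min
    persistence: float = 0.0
    drift_direction: tuple[float, float, float] | None = None
    drift_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must cover at least one step")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be >= 0")
        if not (0.0 <= self.persistence <= 1.0 and 0.0 <= self.drift_weight <= 1.0):
            raise ValueError("persistence and drift_weight must lie in [0, 1]")
        if self.persistence + self.drift_weight > 1.0 + 1e-12:
            raise ValueError("persistence + drift_weight must be <= 1 (convex mix)")
        if self.drift_weight > 0:
            if self.drift_direction is None:
                raise ValueError("drift_weight > 0 requires a drift_direction")
            d = np.asarray(self.drift_direction, dtype=float)
            if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-6:
                raise ValueError("drift_direction must be a unit 3-vector")
        if self.speed_mean == 0 and self.speed_sd == 0:
            raise ValueError("degenerate walk: zero speed and zero speed spread")


def _step_lengths(rng: np.random.Generator, mu: float, sd: float, size) -> np.ndarray:
    """Positive step lengths ~ normal(mu, sd) truncated at zero."""
    if sd == 0.0:
        return np.full(size, mu)
    a = (0.0 - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero draw is astronomically unlikely; guard anyway
    norm[norm == 0] = 1.0
    return v / norm


def generate_walks(params: WalkParams) -> pd.DataFrame:
    """Generate a track table of 3D persistent random walks.

    All tracks start at the origin.  The same seed always yields the same
    table.  Returns a long-format DataFrame with columns
    ``track_id, t, x, y, z`` (t in minutes, positions in µm).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_tracks
    n_steps = int(round(params.duration / params.dt))
    mu = params.speed_mean * params.dt
    sd = params.speed_sd * params.dt

    p, w = params.persistence, params.drift_weight
    noise_w = 1.0 - p - w
    drift = (
        np.asarray(params.drift_direction, dtype=float)
        if params.drift_direction is not None
        else np.zeros(3)
    )

    pos = np.zeros((n, n_steps + 1, 3))
    prev_dir = _random_unit_vectors(rng, n)
    for i in range(n_steps):
        mix = p * prev_dir + w * drift + noise_w * _random_unit_vectors(rng, n)
        norm = np.linalg.norm(mix, axis=1, keepdims=True)
        degenerate = norm[:, 0] < 1e-12
        if np.any(degenerate):
            mix[degenerate] = _random_unit_vectors(rng, int(degenerate.sum()))
            norm = np.linalg.norm(mix, axis=1, keepdims=True)
        direction = mix / norm
        length = _step_lengths(rng, mu, sd, n)
        pos[:, i + 1] = pos[:, i] + direction * length[:, None]
        prev_dir = direction

    width = len(str(n - 1)) if n > 1 else 1
    ids = np.repeat([f"track_{i:0{width}d}" for i in range(n)], n_steps + 1)
    t = np.tile(np.arange(n_steps + 1) * params.dt, n)
    flat = pos.reshape(-1, 3)
    return pd.DataFrame(
        {"track_id": ids, "t": t, "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )


def undirected_walk_params(seed: int, n_tracks: int = 150, duration: float = 30.0) -> WalkParams:
    """Preset emulating the undirected (no-tumouroid) source pool."""
    return WalkParams(
        n_tracks=n_tracks,
        duration=duration,
        speed_mean=_SPEED_MEAN,
        speed_sd=_SPEED_SD,
        persistence=_PERSISTENCE,
        seed=seed,
    )


def chemotactic_walk_params(seed: int, n_tracks: int = 150, duration: float = 30.0) -> WalkParams:
    """Preset emulating the chemotactic source pool (biased toward −x)."""
    return WalkParams(
        n_tracks=n_tracks,
        duration=duration,
        speed_mean=_SPEED_MEAN,
        speed_sd=_SPEED_SD,
        persistence=_PERSISTENCE,
        drift_direction=(REFERENCE_DIRECTION[0], REFERENCE_DIRECTION[1], 0.0),
        drift_weight=_CHEMOTACTIC_DRIFT,
        seed=seed,
    )
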