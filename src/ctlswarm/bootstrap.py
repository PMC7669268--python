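"""Bootstrapped motility: 10-minute blocks of track displacements.

The simulator does not use a parametric motility model.  Instead each
agent repeatedly samples, with replacement, 10-minute blocks of step
displacements cut from a pool of source tracks and re-enacts them.  The
pool comprises every consecutive 10-minute window of every source track
(sliding one sample at a time).  A chemotactic block carries the
direction that pointed toward the attraction target in the source data;
on replay it is rotated about the z axis so that this reference direction
lines up with the local chemokine gradient — "up" is preserved, step
lengths and z components are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .synthetic import REFERENCE_DIRECTION
from .tracks import track_sampling_interval, validate_tracks

__all__ = [
    "PoolKind",
    "MotilityBlock",
    "BlockPool",
    "build_block_pool",
    "sample_block",
    "reorient_block",
    "rotate_steps_z",
    "replay_blocks",
]


class PoolKind(str, Enum):
    UNDIRECTED = "undirected"
    CHEMOTACTIC = "chemotactic"


@dataclass(frozen=True)
class MotilityBlock:
    """One 10-minute window of step displacements from a source track.

    ``steps`` is a (k, 3) array of per-interval displacements in µm;
    ``reference_direction`` is the unit xy direction that pointed toward
    the attraction target when the source was recorded.
    """

    steps: np.ndarray
    reference_direction: tuple[float, float]
    source_track: object
    source_offset: int

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=float)
        if steps.ndim != 2 or steps.shape[1] != 3:
            raise ValueError("block steps must be a (k, 3) array")
        if not np.all(np.isfinite(steps)):
            raise ValueError("block steps must be finite")
        ref = np.asarray(self.reference_direction, dtype=float)
        if ref.shape != (2,) or abs(np.linalg.norm(ref) - 1.0) > 1e-9:
            raise ValueError("reference_direction must be a unit 2-vector")
        object.__setattr__(self, "steps", steps)


@dataclass(frozen=True)
class BlockPool:
    """Pool of motility blocks sampled with replacement by the simulator.

    ``steps`` stacks all blocks as a (n_blocks, k, 3) array for fast
    vectorised sampling; per-block provenance lives in ``source_tracks``
    and ``source_offsets``.
    """

    steps: np.ndarray                     # (n_blocks, k, 3)
    kind: PoolKind
    dt: float                             # min
    block_duration: float                 # min
    reference_direction: tuple[float, float]
    source_tracks: tuple
    source_offsets: np.ndarray

    def __post_init__(self) -> None:
        if len(self.steps) == 0:
            raise ValueError("cannot build an empty block pool (nothing to bootstrap)")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def steps_per_block(self) -> int:
        return self.steps.shape[1]

    def block(self, i: int) -> MotilityBlock:
        return MotilityBlock(
            steps=self.steps[i],
            reference_direction=self.reference_direction,
            source_track=self.source_tracks[i],
            source_offset=int(self.source_offsets[i]),
        )


def build_block_pool(
    tracks: pd.DataFrame,
    kind: PoolKind | str = PoolKind.UNDIRECTED,
    block_duration: float = 10.0,
    reference_direction: tuple[float, float] = REFERENCE_DIRECTION,
) -> BlockPool:
    """Cut every consecutive ``block_duration`` window from a track table.

    A track with n position samples and k = block_duration/dt steps per
    block contributes max(0, n − k) blocks, sliding the window one sample
    at a time.  Raises if no track is long enough.
    """
    kind = PoolKind(kind)
    tracks = validate_tracks(tracks)
    dt = track_sampling_interval(tracks)
    k_f = block_duration / dt
    k = int(round(k_f))
    if abs(k_f - k) > 1e-6 or k < 1:
        raise ValueError(
            f"block_duration ({block_duration} min) must be a positive multiple "
            f"of the track sampling interval ({dt} min)"
        )
    ref = np.asarray(reference_direction, dtype=float)
    ref = tuple(ref / np.linalg.norm(ref))

    all_steps, sources, offsets = [], [], []
    for tid, grp in tracks.groupby("track_id", sort=False):
        pos = grp[["x", "y", "z"]].to_numpy()
        diffs = np.diff(pos, axis=0)            # (n-1, 3)
        n_blocks = len(pos) - k                 # = max windows of k steps
        if n_blocks <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(diffs, (k, 3)).reshape(-1, k, 3)
        all_steps.append(windows.copy())
        sources.extend([tid] * n_blocks)
        offsets.extend(range(n_blocks))

    if not all_steps:
        raise ValueError("no track is long enough to contribute a block; cannot bootstrap")
    return BlockPool(
        steps=np.concatenate(all_steps, axis=0),
        kind=kind,
        dt=dt,
        block_duration=block_duration,
        reference_direction=ref,
        source_tracks=tuple(sources),
        source_offsets=np.asarray(offsets),
    )


def sample_block(pool: BlockPool, rng: np.random.Generator) -> MotilityBlock:
    """Uniform draw with replacement from the pool."""
    return pool.block(int(rng.integers(len(pool))))


def rotate_steps_z(steps: np.ndarray, angle: float) -> np.ndarray:
    """Rotate displacement vectors about the z axis by ``angle`` radians."""
    c, s = np.cos(angle), np.sin(angle)
    out = np.array(steps, dtype=float, copy=True)
    x, y = out[..., 0].copy(), out[..., 1].copy()
    out[..., 0] = c * x - s * y
    out[..., 1] = s * x + c * y
    return out


def reorient_block(block: MotilityBlock, target_direction) -> np.ndarray:
    """Rotate a block's steps so its reference direction becomes ``target``.

    Pure rotation about z (no reflection): z components and step lengths
    are preserved exactly.
    """
    tgt = np.asarray(target_direction, dtype=float)
    norm = np.linalg.norm(tgt)
    if norm < 1e-12:
        raise ValueError("target direction must be nonzero")
    tgt = tgt / norm
    ref = np.asarray(block.reference_direction, dtype=float)
    angle = np.arctan2(tgt[1], tgt[0]) - np.arctan2(ref[1], ref[0])
    return rotate_steps_z(block.steps, angle)


def replay_blocks(blocks, start: np.ndarray) -> np.ndarray:
    """Re-enact a sequence of blocks end-to-end from ``start``.

    Returns the (1 + total_steps, 3) array of visited positions; with
    target = reference on a track's own consecutive blocks this
    reconstructs the source track exactly.
    """
    steps = np.concatenate([np.asarray(b.steps if isinstance(b, MotilityBlock) else b) for b in blocks])
    seq = np.vstack([np.asarray(start, dtype=float)[None, :], steps])
    # sequential accumulation: position i+1 = position i + step i, bit-for-bit
    return np.cumsum(seq, axis=0)
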