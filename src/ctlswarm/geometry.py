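"""Arena geometry shared by the simulator and every metric.

The experimental chamber is a closed cylindrical well containing a
concentric cylindrical tumouroid, both of the same height.  All distances
are in micrometres.  The signed radial coordinate used throughout the
package is the in-plane (xy) distance to the tumouroid interface circle:
negative inside the tumouroid, zero on the interface, positive outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaConfig",
    "radial_distance",
    "inside_tumouroid",
    "um2_per_s_to_cm2_per_s",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Cylindrical well with a concentric tumouroid disc.

    Defaults are the full-scale chamber: a 6.8 mm diameter well containing
    a 2.4 mm diameter tumouroid, both 60 µm high.

    Parameters
    ----------
    well_diameter : float
        Diameter of the outer well, µm.
    tumouroid_diameter : float
        Diameter of the central tumouroid region, µm.
    height : float
        Height of the chamber (z extent), µm.
    centre : tuple of float
        xy coordinates of the common axis, µm.
    """

    well_diameter: float = 6800.0
    tumouroid_diameter: float = 2400.0
    height: float = 60.0
    centre: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.well_diameter > 0 and self.tumouroid_diameter > 0 and self.height > 0):
            raise ValueError("all arena lengths must be positive")
        if not self.tumouroid_diameter < self.well_diameter:
            raise ValueError(
                f"tumouroid_diameter ({self.tumouroid_diameter}) must be smaller "
                f"than well_diameter ({self.well_diameter})"
            )
        if not np.all(np.isfinite(self.centre)):
            raise ValueError("arena centre must be finite")

    @property
    def well_radius(self) -> float:
        return self.well_diameter / 2.0

    @property
    def tumouroid_radius(self) -> float:
        return self.tumouroid_diameter / 2.0

    @classmethod
    def desk_scale(cls) -> "ArenaConfig":
        """Quarter-area arena (half linear scale) for desk-sized runs."""
        return cls(well_diameter=3400.0, tumouroid_diameter=1200.0)


def _as_xy(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] < 2:
        raise ValueError("points must have at least x and y coordinates")
    xy = p[..., :2]
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates")
    return xy


def radial_distance(p, arena: ArenaConfig):
    """Signed in-plane distance from ``p`` to the tumouroid interface, µm.

    Negative inside the tumouroid, 0 on the interface circle, positive
    outside.  Accepts a single point or an array of points (last axis is
    the coordinate axis; z, if present, is ignored).
    """
    xy = _as_xy(p)
    rho = np.hypot(xy[..., 0] - arena.centre[0], xy[..., 1] - arena.centre[1])
    out = rho - arena.tumouroid_radius
    return float(out) if out.ndim == 0 else out


def inside_tumouroid(p, arena: ArenaConfig):
    """True iff ``p`` lies strictly inside the tumouroid disc.

    Points exactly on the interface count as outside, so "infiltrated"
    always means strictly interior.
    """
    d = radial_distance(p, arena)
    return d < 0.0 if np.isscalar(d) else np.asarray(d) < 0.0


def um2_per_s_to_cm2_per_s(d_um2_s: float) -> float:
    """Convert a diffusion coefficient from µm²/s to cm²/s (1 cm = 1e4 µm)."""
    return d_um2_s * 1e-8
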