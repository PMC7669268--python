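"""Diffusing chemokine field built from point secretion events.

Secreting agents deposit discrete quantities of chemokine; the
concentration anywhere is the superposition of the free-space heat kernel
over all past events:

    C(x, t) = sum_e  q_e (4 pi D (t - t_e))^(-3/2) exp(-|x - x_e|^2 / (4 D (t - t_e)))

with D the diffusion coefficient (250 µm²/s for ~10 kDa chemokines such
as CCL3/CCL4) and q_e in molecules, giving concentrations in
molecules/µm³.  There is no degradation and no boundary interaction (the
free-space kernel is used even though the arena walls are impermeable to
cells).

Agents sense the field at the six points where their spherical surface
meets the ±x, ±y, ±z axes; the gradient is formed by central differences
over those probes.  Per-agent sensitivity is heterogeneous: each agent
draws a chemotaxis-actuation threshold and a higher desensitisation
threshold from log-normal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DIFFUSION_COEFFICIENT",
    "SecretionEvent",
    "ThresholdParams",
    "ChemokineField",
    "sample_thresholds",
    "sample_threshold_arrays",
    "point_source_concentration",
]

#: µm²/s, appropriate for ~10 kDa chemokines (equals 2.5e-6 cm²/s)
DEFAULT_DIFFUSION_COEFFICIENT = 250.0

#: gradient magnitudes below this are treated as a tie (no direction)
_GRADIENT_TIE = 1e-30

# events processed per vectorised chunk when answering large queries
_CHUNK = 4_000_000


@dataclass(frozen=True)
class SecretionEvent:
    """One recorded secretion: where, when (seconds) and how much."""

    position: tuple[float, float, float]
    time: float          # s
    quantity: float      # molecules

    def __post_init__(self) -> None:
        if self.quantity <= 0:
            raise ValueError("secretion quantity must be positive")
        if self.time < 0:
            raise ValueError("secretion time must be >= 0")


@dataclass(frozen=True)
class ThresholdParams:
    """Log-normal parameters of per-agent sensing thresholds.

    Medians are in molecules/µm³; ``sigma_log`` is the shared log-space
    standard deviation.  Defaults are calibrated from the field's own
    scales: one agent secreting 1000 molecules/min sustains a steady-state
    concentration of ~5.3e-3/r molecules/µm³ at distance r µm, so an
    actuation median of 1e-6 makes a single secreting agent perceptible
    within ~1 mm, while a desensitisation median of 1e-3 is exceeded only
    in the near field of a large accumulation of secreting agents.
    """

    actuation_median: float = 1e-6
    desensitisation_median: float = 1e-3
    sigma_log: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.actuation_median < self.desensitisation_median):
            raise ValueError("require 0 < actuation_median < desensitisation_median")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


def sample_threshold_arrays(
    params: ThresholdParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (actuation, desensitisation) pairs, rejecting inverted pairs."""
    act = params.actuation_median * np.exp(params.sigma_log * rng.standard_normal(n))
    des = params.desensitisation_median * np.exp(params.sigma_log * rng.standard_normal(n))
    bad = act >= des
    while np.any(bad):
        m = int(bad.sum())
        act[bad] = params.actuation_median * np.exp(params.sigma_log * rng.standard_normal(m))
        des[bad] = params.desensitisation_median * np.exp(params.sigma_log * rng.standard_normal(m))
        bad = act >= des
    return act, des


def sample_thresholds(params: ThresholdParams, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one agent's (actuation, desensitisation) threshold pair."""
    act, des = sample_threshold_arrays(params, 1, rng)
    return float(act[0]), float(des[0])


def point_source_concentration(q: float, d2: np.ndarray, dt_s: np.ndarray, D: float) -> np.ndarray:
    """Heat-kernel concentration of one event: q, squared distance, elapsed s."""
    denom = 4.0 * D * dt_s
    return q * (np.pi * denom) ** -1.5 * np.exp(-d2 / denom)


class ChemokineField:
    """Append-only log of secretion events with heat-kernel queries.

    Events from the same source that fall within ``coalescing_window``
    minutes and ``merge_radius`` µm of that source's previous event are
    merged (quantities summed, position and time quantity-weight
    averaged) to keep the event list — and hence every concentration
    query — tractable.  Set ``coalescing_window=0`` to disable merging
    and make superposition exact.
    """

    def __init__(
        self,
        diffusion_coefficient: float = DEFAULT_DIFFUSION_COEFFICIENT,
        coalescing_window: float = 5.0,     # min
        merge_radius: float = 6.0,          # µm (one agent radius)
    ) -> None:
        if diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if coalescing_window < 0 or merge_radius < 0:
            raise ValueError("coalescing parameters must be >= 0")
        self.D = float(diffusion_coefficient)
        self.coalescing_window = float(coalescing_window)
        self.merge_radius = float(merge_radius)
        self._cap = 1024
        self._n = 0
        self._pos = np.empty((self._cap, 3))
        self._time = np.empty(self._cap)
        self._qty = np.empty(self._cap)
        self._last_by_source: dict = {}

    # -- bookkeeping ---------------------------------------------------

    def __len__(self) -> int:
        return self._n

    @property
    def total_quantity(self) -> float:
        return float(self._qty[: self._n].sum())

    @property
    def events(self) -> list[SecretionEvent]:
        return [
            SecretionEvent(tuple(self._pos[i]), float(self._time[i]), float(self._qty[i]))
            for i in range(self._n)
        ]

    def _grow(self, extra: int) -> None:
        need = self._n + extra
        if need <= self._cap:
            return
        while self._cap < need:
            self._cap *= 2
        for name in ("_pos", "_time", "_qty"):
            old = getattr(self, name)
            new = np.empty((self._cap,) + old.shape[1:])
            new[: self._n] = old[: self._n]
            setattr(self, name, new)

    # -- recording -----------------------------------------------------

    def record_secretion(self, position, time: float, quantity: float, source=None) -> None:
        """Append one secretion event, merging with the source's last event
        when it lies within the coalescing window and merge radius."""
        if quantity <= 0:
            raise ValueError("secretion quantity must be positive")
        if time < 0:
            raise ValueError("secretion time must be >= 0")
        pos = np.asarray(position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("secretion position must be a finite 3-vector")

        if source is not None and self.coalescing_window > 0:
            j = self._last_by_source.get(source)
            if j is not None:
                dt_min = (time - self._time[j]) / 60.0
                if dt_min <= self.coalescing_window and (
                    np.linalg.norm(pos - self._pos[j]) <= self.merge_radius
                ):
                    q0 = self._qty[j]
                    q = q0 + quantity
                    self._pos[j] = (q0 * self._pos[j] + quantity * pos) / q
                    self._time[j] = (q0 * self._time[j] + quantity * time) / q
                    self._qty[j] = q
                    return
        self._grow(1)
        self._pos[self._n] = pos
        self._time[self._n] = time
        self._qty[self._n] = quantity
        if source is not None:
            self._last_by_source[source] = self._n
        self._n += 1

    # -- queries -------------------------------------------------------

    def concentration(self, x, t: float):
        """Concentration (molecules/µm³) at point(s) ``x`` and time ``t`` s.

        ``x`` may be a single 3-point or an (n, 3) array.  Events at or
        after ``t`` contribute nothing.
        """
        if t < 0:
            raise ValueError("query time must be >= 0")
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        scalar = np.asarray(x).ndim == 1
        out = np.zeros(len(pts))
        m = self._n
        if m:
            active = self._time[:m] < t
            ep = self._pos[:m][active]
            et = self._time[:m][active]
            eq = self._qty[:m][active]
            if len(ep):
                step = max(1, _CHUNK // max(1, len(pts)))
                for lo in range(0, len(ep), step):
                    hi = lo + step
                    d2 = ((pts[:, None, :] - ep[None, lo:hi, :]) ** 2).sum(axis=2)
                    c = point_source_concentration(eq[lo:hi][None, :], d2, (t - et[lo:hi])[None, :], self.D)
                    out += c.sum(axis=1)
        return float(out[0]) if scalar else out

    def gradient_probe(self, centre, radius: float, t: float):
        """Six-point probe around a sphere of ``radius`` at ``centre``.

        Evaluates the concentration where the sphere meets the ±x, ±y, ±z
        axes, forms the gradient by central differences, and returns
        ``(direction, max_concentration)`` where direction is a unit
        3-vector or None when the gradient is a numerical tie.
        """
        if radius <= 0:
            raise ValueError("probe radius must be positive")
        c = np.asarray(centre, dtype=float)
        offsets = np.vstack([np.eye(3), -np.eye(3)]) * radius
        conc = self.concentration(c[None, :] + offsets, t)
        grad = (conc[:3] - conc[3:]) / (2.0 * radius)
        norm = np.linalg.norm(grad)
        direction = None if norm < _GRADIENT_TIE else grad / norm
        return direction, float(conc.max(initial=0.0))

    # -- serialisation -------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        """Event log as a DataFrame (x, y, z µm; time s; quantity molecules)."""
        m = self._n
        return pd.DataFrame(
            {
                "x": self._pos[:m, 0],
                "y": self._pos[:m, 1],
                "z": self._pos[:m, 2],
                "time": self._time[:m],
                "quantity": self._qty[:m],
            }
        )

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, diffusion_coefficient: float = DEFAULT_DIFFUSION_COEFFICIENT
    ) -> "ChemokineField":
        field = cls(diffusion_coefficient=diffusion_coefficient, coalescing_window=0.0)
        for row in table.itertuples(index=False):
            field.record_secretion((row.x, row.y, row.z), row.time, row.quantity)
        return field
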