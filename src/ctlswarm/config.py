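"""Simulation configuration, YAML parsing and serialisation.

The configuration file is a flat key-value YAML document; unknown keys
are rejected so typos cannot silently fall back to defaults.  The default
configuration is the desk-scale setup (2,000 agents in a quarter-area
arena); :meth:`SimulationConfig.full_scale` gives the full chamber with
35,000 agents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum

import yaml

from .chemokine import DEFAULT_DIFFUSION_COEFFICIENT, ThresholdParams
from .geometry import ArenaConfig

__all__ = ["Scenario", "SimulationConfig", "parse_config", "serialise_config", "config_hash"]


class Scenario(str, Enum):
    NO_ATTRACTION = "no_attraction"
    POSITIVE_ATTRACTION = "positive_attraction"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    Units: lengths µm, times as annotated (dynamics step in seconds,
    durations and intervals in minutes), speeds µm/min, secretion
    molecules/min, diffusion µm²/s.
    """

    arena: ArenaConfig = field(default_factory=ArenaConfig.desk_scale)
    n_agents: int = 2000
    agent_diameter: float = 12.0        # µm
    dt: float = 20.0                    # s
    record_interval: float = 5.0        # min
    record_plane_z: float = 30.0        # µm
    duration: float = 480.0             # min
    scenario: Scenario = Scenario.NO_ATTRACTION
    seed: int = 0
    intratumoural_speed: float = 0.15   # µm/min, drift toward tumouroid centre
    secretion_rate: float = 1000.0      # molecules/min
    diffusion_coefficient: float = DEFAULT_DIFFUSION_COEFFICIENT  # µm²/s
    threshold_params: ThresholdParams = field(default_factory=ThresholdParams)
    event_coalescing_window: float = 5.0  # min

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.agent_diameter <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("agent_diameter, dt and duration must be positive")
        if not 0 < self.record_plane_z < self.arena.height:
            raise ValueError("record_plane_z must lie strictly inside the arena height")
        steps_per_record = self.record_interval * 60.0 / self.dt
        if abs(steps_per_record - round(steps_per_record)) > 1e-9:
            raise ValueError("dt must divide record_interval")
        if self.intratumoural_speed < 0 or self.secretion_rate <= 0:
            raise ValueError("intratumoural_speed must be >= 0 and secretion_rate > 0")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive")
        if self.event_coalescing_window < 0:
            raise ValueError("event_coalescing_window must be >= 0")

    @property
    def agent_radius(self) -> float:
        return self.agent_diameter / 2.0

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 60.0 / self.dt))

    @property
    def steps_per_record(self) -> int:
        return int(round(self.record_interval * 60.0 / self.dt))

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationConfig":
        """Full-chamber configuration: 35,000 agents in the 6.8 mm well."""
        overrides.setdefault("arena", ArenaConfig())
        overrides.setdefault("n_agents", 35000)
        return cls(**overrides)


# flat-key schema: key -> (target, attribute)
_ARENA_KEYS = {"well_diameter", "tumouroid_diameter", "height"}
_THRESHOLD_KEYS = {"actuation_median", "desensitisation_median", "sigma_log"}
_CONFIG_KEYS = {
    "n_agents", "agent_diameter", "dt", "record_interval", "record_plane_z",
    "duration", "scenario", "seed", "intratumoural_speed", "secretion_rate",
    "diffusion_coefficient", "event_coalescing_window",
}


def parse_config(path) -> SimulationConfig:
    """Parse a flat YAML config; missing keys take defaults, unknown keys fail."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc = {} if doc is None else dict(doc)
    unknown = set(doc) - _ARENA_KEYS - _THRESHOLD_KEYS - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        arena = (
            ArenaConfig(**{k: doc[k] for k in _ARENA_KEYS & set(doc)})
            if _ARENA_KEYS & set(doc)
            else ArenaConfig.desk_scale()
        )
        thresholds = ThresholdParams(**{k: doc[k] for k in _THRESHOLD_KEYS & set(doc)})
        return SimulationConfig(
            arena=arena,
            threshold_params=thresholds,
            **{k: doc[k] for k in _CONFIG_KEYS & set(doc)},
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration ({path}): {exc}") from exc


def _flatten(config: SimulationConfig) -> dict:
    return {
        "well_diameter": config.arena.well_diameter,
        "tumouroid_diameter": config.arena.tumouroid_diameter,
        "height": config.arena.height,
        "n_agents": config.n_agents,
        "agent_diameter": config.agent_diameter,
        "dt": config.dt,
        "record_interval": config.record_interval,
        "record_plane_z": config.record_plane_z,
        "duration": config.duration,
        "scenario": config.scenario.value,
        "seed": config.seed,
        "intratumoural_speed": config.intratumoural_speed,
        "secretion_rate": config.secretion_rate,
        "diffusion_coefficient": config.diffusion_coefficient,
        "actuation_median": config.threshold_params.actuation_median,
        "desensitisation_median": config.threshold_params.desensitisation_median,
        "sigma_log": config.threshold_params.sigma_log,
        "event_coalescing_window": config.event_coalescing_window,
    }


def serialise_config(config: SimulationConfig, path) -> None:
    """Write a config as flat YAML; parse_config round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(_flatten(config), fh, sort_keys=True)


def config_hash(config: SimulationConfig) -> str:
    """Stable digest of all configuration values (for run manifests)."""
    payload = json.dumps(_flatten(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
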