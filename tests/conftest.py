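import numpy as np
import pandas as pd
import pytest

from ctlswarm import (
    ArenaConfig,
    SimulationConfig,
    build_block_pool,
    chemotactic_walk_params,
    generate_walks,
    undirected_walk_params,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def arena():
    """Full-scale arena: 6.8 mm well, 2.4 mm tumouroid."""
    return ArenaConfig()


@pytest.fixture(scope="session")
def desk_arena():
    return ArenaConfig.desk_scale()


@pytest.fixture(scope="session")
def small_tracks():
    """Small undirected synthetic track table (20 tracks x 15 min at 20 s)."""
    return generate_walks(undirected_walk_params(seed=11, n_tracks=20, duration=15))


@pytest.fixture(scope="session")
def small_pools(small_tracks):
    und = build_block_pool(small_tracks, kind="undirected")
    chem = build_block_pool(
        generate_walks(chemotactic_walk_params(seed=12, n_tracks=20, duration=15)),
        kind="chemotactic",
    )
    return und, chem


@pytest.fixture()
def tiny_config():
    """Tiny arena / few agents — runs in well under a second."""
    return SimulationConfig(
        arena=ArenaConfig(well_diameter=800.0, tumouroid_diameter=300.0),
        n_agents=40,
        duration=10.0,
        seed=5,
    )


def make_tracks(points_by_id):
    """Build a track table from {track_id: [(t, x, y, z), ...]}."""
    rows = [
        (tid, *pt) for tid, pts in points_by_id.items() for pt in pts
    ]
    return pd.DataFrame(rows, columns=["track_id", "t", "x", "y", "z"])
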