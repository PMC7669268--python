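"""Agent-based engine for T-cell swarming around a tumouroid.

Agents are non-overlapping 12 µm spheres moving in a closed cylindrical
well with a concentric tumouroid region.  Outside the tumouroid an agent
re-enacts bootstrapped 10-minute motility blocks; it replays chemotactic
blocks (reoriented toward the local chemokine gradient) while the maximum
concentration perceived at its six sphere-surface probe points lies
between its personal actuation and desensitisation thresholds, and
undirected blocks (after a uniformly random rotation about z) otherwise.
An agent entering the tumouroid abandons block replay permanently and
creeps toward the tumouroid centre in the xy plane at 0.15 µm/min; in the
positive-attraction scenario it also secretes chemokine at
1000 molecules/min, closing the recruitment feedback loop.  In the
no-attraction scenario nothing is ever secreted.

State is updated in 20 s increments; the xy positions of agents whose
sphere intersects the recording plane (z = 30 µm by default) are recorded
every 5 minutes, mirroring whole-well imaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .bootstrap import BlockPool, MotilityBlock, rotate_steps_z
from .chemokine import ChemokineField, sample_threshold_arrays
from .config import Scenario, SimulationConfig
from .geometry import ArenaConfig
from .tracks import Frame

__all__ = [
    "MODE_UNDIRECTED",
    "MODE_CHEMOTACTIC",
    "MODE_INTRATUMOURAL",
    "AgentState",
    "SimulationState",
    "initialise",
    "step",
    "resolve_move",
    "run",
]

MODE_UNDIRECTED = 0
MODE_CHEMOTACTIC = 1
MODE_INTRATUMOURAL = 2

_MODE_NAMES = {0: "undirected", 1: "chemotactic", 2: "intratumoural"}

#: gradient (or xy-projection) norms below this count as "no direction"
_TIE = 1e-30


@dataclass(frozen=True)
class AgentState:
    """Read-only snapshot of a single agent."""

    position: np.ndarray
    mode: str
    actuation: float
    desensitisation: float
    current_block: MotilityBlock | None
    block_cursor: int
    block_target: tuple[float, float] | None


class SimulationState:
    """Mutable state of one run; built by :func:`initialise`.

    Agent attributes are stored as parallel arrays (struct-of-arrays) for
    speed; :attr:`agents` materialises per-agent snapshots on demand.
    """

    def __init__(self, config, undirected_pool, chemotactic_pool, rng_dynamics,
                 pos, mode, actuation, desensitisation,
                 steps_buf, cursor, block_idx, block_target):
        self.config = config
        self.undirected_pool = undirected_pool
        self.chemotactic_pool = chemotactic_pool
        self.rng = rng_dynamics
        self.t = 0.0                          # s
        self.pos = pos                        # (n, 3) µm
        self.mode = mode                      # (n,) int8
        self.actuation = actuation            # (n,) molecules/µm³
        self.desensitisation = desensitisation
        self.steps_buf = steps_buf            # (n, k, 3) oriented block steps
        self.cursor = cursor                  # (n,) next step index
        self.block_idx = block_idx            # (n,) index into source pool
        self.block_target = block_target      # (n, 2) xy target, NaN if none
        self.field = ChemokineField(
            diffusion_coefficient=config.diffusion_coefficient,
            coalescing_window=config.event_coalescing_window,
            merge_radius=config.agent_radius,
        )
        self.n_chemotactic_agent_steps = 0

    @property
    def n_agents(self) -> int:
        return len(self.pos)

    @property
    def steps_per_block(self) -> int:
        return self.steps_buf.shape[1]

    @property
    def agents(self) -> list[AgentState]:
        out = []
        for i in range(self.n_agents):
            m = int(self.mode[i])
            if m == MODE_INTRATUMOURAL:
                block, target = None, None
            else:
                pool = self.chemotactic_pool if m == MODE_CHEMOTACTIC else self.undirected_pool
                block = pool.block(int(self.block_idx[i]))
                target = (
                    tuple(self.block_target[i])
                    if np.all(np.isfinite(self.block_target[i]))
                    else None
                )
            out.append(
                AgentState(
                    position=self.pos[i].copy(),
                    mode=_MODE_NAMES[m],
                    actuation=float(self.actuation[i]),
                    desensitisation=float(self.desensitisation[i]),
                    current_block=block,
                    block_cursor=int(self.cursor[i]),
                    block_target=target,
                )
            )
        return out

    def assert_no_overlap(self) -> None:
        """Raise if any two agent centres are closer than one diameter."""
        tree = cKDTree(self.pos)
        pairs = tree.query_pairs(self.config.agent_diameter * (1 - 1e-9))
        if pairs:
            raise AssertionError(f"overlapping agents: {sorted(pairs)[:5]}")


def _check_pools(config: SimulationConfig, *pools: BlockPool) -> int:
    ks = set()
    for pool in pools:
        if abs(pool.dt * 60.0 - config.dt) > 1e-6 * config.dt:
            raise ValueError(
                f"pool sampling interval ({pool.dt} min) does not match the "
                f"simulation step ({config.dt} s)"
            )
        ks.add(pool.steps_per_block)
    if len(ks) != 1:
        raise ValueError("undirected and chemotactic pools must share a block length")
    return ks.pop()


def _project_to_arena(pos: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    """Project positions to the nearest interior point of the well cylinder."""
    out = np.atleast_2d(np.asarray(pos, dtype=float)).copy()
    cx, cy = arena.centre
    dx, dy = out[:, 0] - cx, out[:, 1] - cy
    rho = np.hypot(dx, dy)
    over = rho > arena.well_radius
    if np.any(over):
        scale = arena.well_radius / rho[over]
        out[over, 0] = cx + dx[over] * scale
        out[over, 1] = cy + dy[over] * scale
    np.clip(out[:, 2], 0.0, arena.height, out=out[:, 2])
    return out


def _sample_oriented_blocks(pool: BlockPool, n: int, rng, angles=None, targets=None):
    """Draw n blocks and orient them: by explicit target xy directions
    (chemotactic) or by uniformly random z-rotation (undirected)."""
    idx = rng.integers(len(pool), size=n)
    steps = pool.steps[idx]
    if targets is not None:
        ref = np.asarray(pool.reference_direction)
        ref_angle = np.arctan2(ref[1], ref[0])
        angles = np.arctan2(targets[:, 1], targets[:, 0]) - ref_angle
    elif angles is None:
        angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    c, s = np.cos(angles)[:, None], np.sin(angles)[:, None]
    x, y = steps[..., 0], steps[..., 1]
    out = np.empty_like(steps)
    out[..., 0] = c * x - s * y
    out[..., 1] = s * x + c * y
    out[..., 2] = steps[..., 2]
    return idx, out


def initialise(
    config: SimulationConfig,
    undirected_pool: BlockPool,
    chemotactic_pool: BlockPool,
) -> SimulationState:
    """Place agents and draw their thresholds and first motility blocks.

    Agents are placed uniformly at random (by volume) in the annulus
    between tumouroid and well wall, rejecting overlaps.  Each agent
    starts undirected partway through a randomly drawn block — random
    initial cursors desynchronise block boundaries so the population does
    not re-probe the chemokine field in lock-step every 10 minutes.
    """
    k = _check_pools(config, undirected_pool, chemotactic_pool)
    arena = config.arena
    n = config.n_agents

    sphere_volume = 4.0 / 3.0 * np.pi * config.agent_radius**3
    annulus_volume = (
        np.pi * (arena.well_radius**2 - arena.tumouroid_radius**2) * arena.height
    )
    if n * sphere_volume > 0.4 * annulus_volume:
        raise ValueError(
            f"packing infeasible: {n} agents of diameter {config.agent_diameter} µm "
            f"exceed 40% of the available annulus volume"
        )

    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_thresh, rng_dyn = (np.random.default_rng(c) for c in ss.spawn(3))

    pos = _place_agents(config, rng_place)
    act, des = sample_threshold_arrays(config.threshold_params, n, rng_thresh)
    block_idx, steps_buf = _sample_oriented_blocks(undirected_pool, n, rng_dyn)
    cursor = rng_dyn.integers(0, k, size=n)
    state = SimulationState(
        config=config,
        undirected_pool=undirected_pool,
        chemotactic_pool=chemotactic_pool,
        rng_dynamics=rng_dyn,
        pos=pos,
        mode=np.full(n, MODE_UNDIRECTED, dtype=np.int8),
        actuation=act,
        desensitisation=des,
        steps_buf=steps_buf,
        cursor=cursor,
        block_idx=block_idx,
        block_target=np.full((n, 2), np.nan),
    )
    return state


def _place_agents(config: SimulationConfig, rng) -> np.ndarray:
    arena = config.arena
    n = config.n_agents
    rt2, rw2 = arena.tumouroid_radius**2, arena.well_radius**2

    def draw(m):
        rho = np.sqrt(rng.uniform(rt2, rw2, size=m))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=m)
        z = rng.uniform(0.0, arena.height, size=m)
        return np.column_stack(
            [arena.centre[0] + rho * np.cos(theta), arena.centre[1] + rho * np.sin(theta), z]
        )

    pos = draw(n)
    for _ in range(1000):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(config.agent_diameter, output_type="ndarray")
        if len(pairs) == 0:
            return pos
        redo = np.unique(pairs[:, 1])       # resample the later index of each pair
        pos[redo] = draw(len(redo))
    raise ValueError("could not place agents without overlap (packing too dense)")


def resolve_move(state: SimulationState, agent_index: int, displacement) -> np.ndarray:
    """Boundary- and collision-resolve one agent's proposed displacement.

    The proposed position is projected to the nearest interior point of
    the well (sliding along walls, floor and ceiling); if it would bring
    the agent's centre within one diameter of any other agent's centre
    the move is rejected and the current position returned unchanged.
    """
    disp = np.asarray(displacement, dtype=float)
    if not np.all(np.isfinite(disp)):
        raise ValueError("displacement must be finite")
    proposed = _project_to_arena(state.pos[agent_index] + disp, state.config.arena)[0]
    others = np.delete(np.arange(state.n_agents), agent_index)
    if len(others):
        d = np.linalg.norm(state.pos[others] - proposed, axis=1)
        if np.any(d < state.config.agent_diameter):
            return state.pos[agent_index].copy()
    return proposed


def _resolve_all_moves(state: SimulationState, proposed: np.ndarray) -> None:
    """Accept or reject all proposed positions, preserving non-overlap.

    Agents with no other agent within one diameter plus twice the largest
    proposed displacement are conflict-free and accepted en bloc; the
    rest are processed sequentially in a seeded random order, each agent
    seeing the already-updated positions of the others.
    """
    diameter = state.config.agent_diameter
    disp_norm = np.linalg.norm(proposed - state.pos, axis=1)
    max_disp = float(disp_norm.max(initial=0.0))
    tree = cKDTree(state.pos)
    pairs = tree.query_pairs(diameter + 2.0 * max_disp, output_type="ndarray")
    if len(pairs) == 0:
        state.pos[:] = proposed
        return
    involved = np.unique(pairs)
    free = np.ones(state.n_agents, dtype=bool)
    free[involved] = False
    state.pos[free] = proposed[free]

    neighbours: dict[int, list[int]] = {int(i): [] for i in involved}
    for a, b in pairs:
        neighbours[int(a)].append(int(b))
        neighbours[int(b)].append(int(a))
    for i in state.rng.permutation(involved):
        i = int(i)
        nb = neighbours[i]
        d = np.linalg.norm(state.pos[nb] - proposed[i], axis=1)
        if not np.any(d < diameter):
            state.pos[i] = proposed[i]


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one dt (20 s by default), in place."""
    cfg = state.config
    arena = cfg.arena
    dt_min = cfg.dt / 60.0
    n = state.n_agents
    k = state.steps_per_block
    cx, cy = arena.centre

    # tumouroid entry interrupts block replay immediately and permanently
    rho = np.hypot(state.pos[:, 0] - cx, state.pos[:, 1] - cy)
    state.mode[rho < arena.tumouroid_radius] = MODE_INTRATUMOURAL
    intra = state.mode == MODE_INTRATUMOURAL

    if cfg.scenario == Scenario.POSITIVE_ATTRACTION and np.any(intra):
        quantity = cfg.secretion_rate * dt_min
        idx = np.flatnonzero(intra)
        _record_secretions(state.field, state.pos[idx], state.t, quantity, idx)

    proposed = state.pos.copy()

    # intratumoural creep toward the centre in xy; z held
    if np.any(intra):
        step_len = cfg.intratumoural_speed * dt_min
        d = np.column_stack([cx - state.pos[intra, 0], cy - state.pos[intra, 1]])
        dist = np.linalg.norm(d, axis=1)
        move = np.minimum(step_len, dist)
        unit = np.divide(d, dist[:, None], out=np.zeros_like(d), where=dist[:, None] > 0)
        proposed[intra, :2] = state.pos[intra, :2] + unit * move[:, None]

    # block-boundary agents: probe the field, re-decide mode, draw a block
    outside = ~intra
    need = np.flatnonzero(outside & (state.cursor >= k))
    if len(need):
        _renew_blocks(state, need)
    state.n_chemotactic_agent_steps += int(np.count_nonzero(state.mode == MODE_CHEMOTACTIC))

    out_idx = np.flatnonzero(outside)
    if len(out_idx):
        proposed[out_idx] = (
            state.pos[out_idx] + state.steps_buf[out_idx, state.cursor[out_idx]]
        )
    proposed = _project_to_arena(proposed, arena)
    _resolve_all_moves(state, proposed)
    state.cursor[out_idx] += 1
    state.t += cfg.dt
    return state


def _record_secretions(field: ChemokineField, positions, t, quantity, sources) -> None:
    pos_list = positions.tolist()
    for i, src in enumerate(sources.tolist()):
        field.record_secretion(pos_list[i], t, quantity, source=src)


def _renew_blocks(state: SimulationState, idx: np.ndarray) -> None:
    """Probe the field at six sphere-surface points per agent, set the
    behavioural mode, and load a freshly oriented block."""
    cfg = state.config
    r = cfg.agent_radius
    m = len(idx)
    offsets = np.vstack([np.eye(3), -np.eye(3)]) * r          # +x,+y,+z,-x,-y,-z
    points = (state.pos[idx][:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    conc = state.field.concentration(points, state.t).reshape(m, 6)
    grad = (conc[:, :3] - conc[:, 3:]) / (2.0 * r)
    grad_norm = np.linalg.norm(grad, axis=1)
    gxy_norm = np.hypot(grad[:, 0], grad[:, 1])
    max_c = conc.max(axis=1)

    chemotactic = (
        (state.actuation[idx] < max_c)
        & (max_c < state.desensitisation[idx])
        & (grad_norm > _TIE)
        & (gxy_norm > _TIE)
    )

    chem = idx[chemotactic]
    und = idx[~chemotactic]
    # draw in a fixed order (chemotactic then undirected) for determinism
    if len(chem):
        targets = grad[chemotactic, :2] / gxy_norm[chemotactic, None]
        bi, steps = _sample_oriented_blocks(
            state.chemotactic_pool, len(chem), state.rng, targets=targets
        )
        state.block_idx[chem] = bi
        state.steps_buf[chem] = steps
        state.block_target[chem] = targets
        state.mode[chem] = MODE_CHEMOTACTIC
    if len(und):
        bi, steps = _sample_oriented_blocks(state.undirected_pool, len(und), state.rng)
        state.block_idx[und] = bi
        state.steps_buf[und] = steps
        state.block_target[und] = np.nan
        state.mode[und] = MODE_UNDIRECTED
    state.cursor[idx] = 0


def run(
    config: SimulationConfig,
    undirected_pool: BlockPool,
    chemotactic_pool: BlockPool,
    return_state: bool = False,
):
    """Run a full simulation, recording frames every ``record_interval``.

    A frame holds the xy positions of agents whose sphere intersects the
    recording plane, i.e. |z − record_plane_z| ≤ agent radius.  The frame
    at t = 0 is included.  Identical (config, pools) give bit-identical
    frames.
    """
    state = initialise(config, undirected_pool, chemotactic_pool)
    frames = [_record_frame(state)]
    for i in range(config.n_steps):
        step(state)
        if (i + 1) % config.steps_per_record == 0:
            frames.append(_record_frame(state))
    return (frames, state) if return_state else frames


def _record_frame(state: SimulationState) -> Frame:
    cfg = state.config
    sel = np.abs(state.pos[:, 2] - cfg.record_plane_z) <= cfg.agent_radius
    return Frame(t=state.t / 60.0, positions=state.pos[sel, :2].copy())
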