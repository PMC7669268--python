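# Methods

`ctlswarm` simulates populations of cytotoxic T lymphocytes (CTLs)
converging on a tumouroid — a dense central mass of tumour cells — and
quantifies that convergence from recorded cell positions.  This note
documents the model, its parameters and units, the synthetic-data
generator, and the numerical and design choices that were genuinely open.

## The agent-based model

**Arena.**  A closed cylindrical well of diameter 6.8 mm containing a
concentric tumouroid region of diameter 2.4 mm, both 60 µm high.  Agents
are non-overlapping spheres of 12 µm diameter.  The full-scale
configuration simulates 35,000 agents; the package's default is a
desk-scale setup of 2,000 agents in a quarter-area arena (3.4 mm well,
1.2 mm tumouroid), which preserves the initial area density of cells
and runs on one CPU core in minutes.  All lengths are µm, public times
minutes, the internal dynamics step seconds, concentrations
molecules/µm³.

**Bootstrapped motility.**  Agents do not follow a parametric random
walk.  Each agent repeatedly draws, with replacement, a 10-minute block
of consecutive step displacements cut from a pool of source tracks and
re-enacts it step by step (20 s per step, so 30 steps per block).  The
pool contains *every* consecutive 10-minute window of every source
track, sliding one sample at a time (a track with n samples contributes
n − 30 blocks): this is the maximal-overlap reading of "all unique
consecutive windows".  Two pools exist: an *undirected* pool from tracks
recorded with no attraction target, and a *chemotactic* pool from tracks
biased toward a target.  A chemotactic block carries the unit xy
direction that pointed toward the target in the source data
(conventionally (−1, 0): the source tumouroid lay toward −x); on replay
the whole block is rotated about the z axis so that this reference
direction coincides with the local chemokine-gradient direction.  "Up"
is preserved — the rotation never touches z components or step lengths.
Undirected blocks are replayed after a uniformly random z-rotation so
that replays do not inherit the source arena's horizontal anisotropy;
this extra randomisation is a package choice, made because block
reference frames of undirected source data are arbitrary.

**Chemokine field.**  Agents inside the tumouroid in the
positive-attraction scenario secrete 1000 molecules/min, deposited as
one event of 1000·dt/60 molecules per 20 s step at the agent's current
position.  The concentration anywhere is the superposition of the
free-space 3D heat kernel over all past events:

    C(x, t) = Σ_e q_e (4πD(t − t_e))^(−3/2) exp(−|x − x_e|² / (4D(t − t_e)))

with D = 250 µm²/s (2.5 × 10⁻⁶ cm²/s, appropriate for ~10 kDa
chemokines such as CCL3/CCL4).  No degradation, and no boundary
interaction: the arena walls are impermeable to agents, but the kernel
is evaluated in free space (no image sources).  To keep the event sum
tractable, consecutive events from the same agent within a 5-minute
window and one agent radius are merged (quantities summed,
position/time quantity-weighted); merging can be disabled, making
superposition exact, and the package verifies linearity both ways.

**Sensing and behavioural modes.**  An agent probes the field at the six
points where its spherical surface meets the ±x, ±y, ±z axes; the
gradient is the central difference over opposing probes.  The agent is
*chemotactic* — replays gradient-oriented chemotactic blocks — only
while the maximum probed concentration lies strictly between its
personal *actuation* and *desensitisation* thresholds and the gradient
has a nonzero xy projection; otherwise it is *undirected*.  Thresholds
are heterogeneous across agents: each is its median times
exp(σ·N(0,1)), with inverted pairs redrawn.

The threshold medians are calibrated from the model's own scales (no
measured values exist for them).  A single agent secreting
1000 molecules/min sustains a steady-state concentration of
q̇/(4πDr) ≈ 5.3 × 10⁻³/r molecules/µm³ at distance r µm.  The defaults

| parameter | default | rationale |
|---|---|---|
| actuation median | 1 × 10⁻⁶ molecules/µm³ | one secreting agent becomes perceptible within ~1 mm after ~20 min — long-range recruitment without instantaneous whole-arena response |
| desensitisation median | 1 × 10⁻³ molecules/µm³ | exceeded only in the near field of ≳100 secreting agents, so only cells closest to a developed swarm lose directionality |
| σ (log-space) | 0.5 | ~threefold spread across agents at ±2σ |

keep the two regimes the model is built around — a far field that
chemotaxes and a saturated near field that reverts to undirected motion
— both realisable inside the arena.  Substantially lower desensitisation
medians (within ~2 decades of actuation) put the whole arena above the
ceiling as soon as a handful of agents secrete, abolishing attraction
entirely.

**Mode re-evaluation and block boundaries.**  The field is probed, and
the mode re-decided, when an agent finishes its current block — not
every 20 s step — consistent with re-enacting whole blocks; the
gradient used to orient a chemotactic block is sampled once at block
start and held for the block.  Tumouroid entry is the one exception: it
interrupts the block immediately.  Agents inside the tumouroid abandon
block replay permanently and creep toward the tumouroid centre in the
xy plane at 0.15 µm/min with z held; there is no exit path.  At
initialisation every agent starts at a uniformly random offset within
its first block, desynchronising block boundaries so the population
does not probe the field in lock-step every 10 minutes.

**Collisions and boundaries.**  A proposed step that would leave the
well cylinder is projected to the nearest interior point (sliding along
the wall, floor or ceiling).  A step that would bring two agent centres
within one diameter is rejected — the agent stays put, its block cursor
still advances.  Moves are resolved in a seeded random order per step;
agents with no candidate neighbour within one diameter plus twice the
largest proposed displacement are provably conflict-free and resolved
in bulk.  The non-overlap invariant holds exactly at every step.  Agent
placement at t = 0 is uniform by volume over the annulus between
tumouroid and wall (CTLs start in the surrounding matrix, not inside
the tumouroid), with overlapping draws rejected.

**Recording.**  Positions update every 20 s, but only the xy locations
of agents whose sphere intersects the plane z = 30 µm
(|z − 30| ≤ 6 µm) are recorded, every 5 min including t = 0 — mirroring
the restricted z-depth of whole-well imaging.  With 2,000 agents in a
60 µm column this samples roughly a fifth of the population per frame,
so any single frame's swarming index carries sampling noise of
SE ≈ 1/√(3n) ≈ 0.03; statements about drift are therefore made on the
time-averaged index, not single frames.

## Quantification

**Swarming index M.**  A per-frame statistic of cell positions relative
to the tumouroid with three anchor values: −1 when all cells sit on the
well perimeter, 0 in expectation when cells are uniform outside the
tumouroid, +1 when all cells are infiltrated.  Only the anchors are
published for this index; the functional form here is the package's
own, chosen as the simplest continuous statistic meeting all three.
Cells inside the tumouroid score +1; a cell outside at in-plane radius
ρ scores 1 − 2u with u = (ρ² − R_t²)/(R_w² − R_t²), the area-fraction
coordinate of the annulus.  Under spatial uniformity u is uniform on
[0, 1], so the score is uniform on [−1, 1] and averages to 0; at the
perimeter u = 1 and the score is −1; the score is continuous across the
tumouroid interface.  M is invariant under rotations about the arena
centre and never decreases when a cell moves strictly inward.  A
different anchor-satisfying form could differ in intermediate regimes;
the anchor tests are the contract.

**FMI.**  The forward migration index of a track is its net
displacement projected on a toward-target unit vector, divided by the
net displacement magnitude — the cosine of the angle between the
displacement and the target direction.  The target vector is always an
explicit argument (classically the x axis toward the tumouroid); no
sign convention is hidden.  Zero-displacement and single-point tracks
are excluded and reported, never silently dropped.  Tracks shorter than
10 min (inclusive boundary: exactly 10 min is kept) are filtered before
population statistics.

**Density kymographs.**  Per frame, the cumulative count N(r) of cells
lying within radial distance r of the tumouroid interface (infiltrated
cells excluded) is computed exactly, smoothed over r with a cubic
penalised smoothing spline (penalty chosen by generalised
cross-validation unless supplied), and differentiated in r.  Dividing
by the circumference 2π(R_t + r) gives a per-area density; both the
per-area and per-r densities are emitted, since either normalisation is
defensible.  Negative post-smoothing densities are clipped to zero and
counted.  The instantaneous-FMI kymograph scores each step displacement
against the inward radial direction at the step's start and reports
binned means over (distance, time); empty bins are NaN, distinguishable
from a genuine zero mean.  A fitted smooth surface over these values is
deliberately out of scope.

**Plate-assay indices.**  Transmigration index = cells transmigrated
toward sample / toward control medium.  Cytotoxicity index (%) =
[1 − (cognate₂ₕ/non-cognate₂ₕ)/(cognate₀ₕ/non-cognate₀ₕ)] × 100.

## Synthetic tracks

The generator replaces the ex vivo source tracks the bootstrap was
designed around.  Each step direction is the normalised convex mix of
the previous direction (weight *persistence*), a fixed drift direction
(weight *drift_weight*) and an isotropic random unit vector (the
remainder); step lengths are draws from a normal(speed·dt, sd·dt)
truncated at zero.  This two-knob family spans undirected to ballistic
motion and reproduces the two statistical features the bootstrap
assumes: short-range directional persistence and (for the chemotactic
pool) a population-level bias toward a fixed reference direction.

Standard study conditions, chosen once from field-typical effector
T-cell motility in 3D collagen: mean speed 4 µm/min, speed SD
1.5 µm/min, persistence 0.4, sampling 20 s, 150 tracks of 30 min per
pool; chemotactic pool drift weight 0.4 toward (−1, 0, 0), giving a
population FMI ≈ 0.3–0.4, the magnitude reported for CTLs near cognate
tumouroids.  What the generator does *not* emulate: speed–turn-angle
coupling, heterogeneity between cells, confinement effects near
collagen fibres, and arrest/contact behaviour.  Tests passing on
synthetic pools therefore validate the machinery (block cutting,
reorientation, replay, sensing, metrics), not any claim about real CTL
track statistics.

## Numerical choices

- Gradient or xy-projection norms below 10⁻³⁰ are ties: the agent acts
  undirected for that decision.
- Probe-based gradients converge to the analytic kernel gradient as the
  probe radius shrinks (verified at 6, 3 and 1.5 µm).
- Frame output is formatted at 6 significant digits; the swarming index
  tolerates the ≤10⁻⁴-relative radius overshoot this rounding can
  produce for wall-hugging cells.
- Reproducibility: one global seed fans out to per-module substreams
  via `numpy.random.SeedSequence(seed).spawn`, so placement,
  thresholds and dynamics are independently reproducible; identical
  (config, pools) give bit-identical frames.
- Desk-scale problem sizes used throughout the test suite: 2,000
  agents, quarter-area arena, 8 simulated hours for scenario-contrast
  checks; tiny arenas (≤0.8 mm) with tens of agents for unit tests.

## Known limitations

- Free-space diffusion ignores the impermeable walls; near-wall
  concentrations are underestimated relative to a reflecting-boundary
  solution.  The choice is the literal reading of the model description,
  which specifies boundaries only for agents.
- Collision resolution by rejection can transiently freeze agents in
  dense packs (e.g. the ring that forms at the tumouroid interface);
  sliding resolution applies only at the arena boundary.
- Intratumoural behaviour is entry-only: no egress, no target lysis, no
  interaction with pre-embedded cells.
- Whether the tumouroid "environment" is a region distinct from the
  tumouroid mass is ambiguous in the source description; the model uses
  a single disc region.
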