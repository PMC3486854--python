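# Methods

`mesotail` simulates actin-based propulsion of micron-scale beads in two
dimensions with a hybrid (mesoscopic) description: the few dozen filament
tips that touch the obstacle are resolved as discrete tethered-ratchet
springs, while the bulk of the comet tail is coarse-grained into a
node-spring gel that assembles at the surface, deforms quasi-statically,
and turns over by stochastic disassembly and crosslink rupture.  This note
records the model, its numerical realization, the calibration of the
defaults, and what the package's synthetic experiments do and do not show.

## The model

**Obstacle.** A rigid ellipse with semi-axes `a ≥ b` (μm), pose `(center,
orientation)`, and overdamped mobilities `μ_t` (μm·s⁻¹·pN⁻¹), `μ_r`
(rad·s⁻¹·(pN·μm)⁻¹).  All surface interactions are normal to the surface,
so contact queries reduce to nearest-point problems on the ellipse, solved
by safeguarded Newton iteration on the surface parameter with a dense-scan
fallback.

**Surface filaments.** Each `Filament` is an effective cluster of barbed
ends, a linear spring of stiffness `κ_f` between a *pointed-end anchor*
(a gel node) and the surface:

* *attached*: tether to a body-fixed site; tension `κ_f·(d − rest)` when
  stretched, never compression; Bell-law detachment
  `k_det0·exp(F/F_d)`.
* *free*: grows at the Brownian-ratchet velocity
  `V_max·exp(−F·δ/k_BT)` under its current push `F`; whenever its
  rest-length tip overlaps the bead by `p > 0` it pushes with `κ_f·p`
  along the inward surface normal (equal and opposite force on the
  anchor).  Free filaments re-attach (`k_att`) or cap (`k_cap`); capping
  removes the filament but leaves its anchor node, which is how surface
  actin matures into bulk gel.

New filaments are born attached and undeformed (`rest = L0`) by two
channels: spontaneous nucleation, uniform per unit arclength (`k_nuc`),
and autocatalytic branching at `k_br` per existing filament, placed a
Gaussian arclength offset `σ_br` from the parent's contact point.  The
defaults put roughly half of all births in each channel, which is the
mixture that produces a coherent tail; either channel alone degenerates
(uniform nucleation never polarizes, pure branching collapses to a point).

**Gel.** Nodes joined by Hookean springs with individual rest lengths.
A new anchor links to up to 4 live nodes within `anchor_radius`, each
spring born at its current length (zero tension).  Turnover: every node is
removed with rate `k_dis` (springs cascade), and any spring whose tension
exceeds `F_rup` ruptures.  Nodes farther than `d_freeze` from the bead
surface freeze irreversibly — the aged tail adhering to the substrate —
which is what gives the tail traction.

**Coupling and motion.** Within a time step: spawn; tau-leap all filament
transitions using the incoming loads; sum the outgoing filament forces
into a bead wrench and per-anchor reactions; relax the gel under those
reactions; move the bead overdamped (`Δx = μ_t F Δt`, `Δθ = μ_r T Δt`);
rupture; disassemble; freeze.  Pushes act at the nearest surface point,
pulls at the attachment site; Newton's third law holds exactly per
filament, so bead force plus total gel reaction vanishes identically.

## Numerical realization

* **Tau-leaping** with per-event Bernoulli/Poisson draws on a fixed Δt;
  all guards (`rate·Δt < 0.2`) are enforced at configuration time.  One
  RNG stream, iteration in id order: a fixed seed reproduces a run
  bit-for-bit.
* **Gel relaxation** is a damped Jacobi sweep (move each node along its
  net force divided by the sum of incident stiffnesses, damping 0.8).
  `GelNetwork.relax` iterates to any requested residual and is verified
  against a dense energy minimizer.  Inside the engine the sweep budget is
  bounded (default 30 sweeps/step at tolerance 1e-2 pN): information then
  travels about one node per sweep, which gives the gel a controlled
  viscous response on short times — the viscoelasticity of a real tail —
  while remaining quasi-static on kinetic time scales.
* **Regularizations.** Two situations have no static equilibrium and are
  given explicit drag instead: an anchor node with no springs yields
  against its own filament's stiffness (it cannot brace against anything),
  and every node's displacement per step is capped at
  `node_drift_speed·Δt`, which lets floating gel fragments drift at a
  bounded rate instead of diverging.
* **Stiff events.** If the bead wrench would move the bead more than
  `0.1·b` in one step (rupture avalanches, heavily loaded tether
  clusters), that step is re-integrated in eight substeps with force
  recomputation and no additional random draws.
* **Contact saturation.** Penetration pushes cap at `5·F_rup`; deep
  overlap is rare and transient, and unbounded Hookean penalties would
  destabilize the explicit scheme.
* Hot loops (nearest-point solves, the fused filament pass, relaxation
  sweeps, turnover/freezing) are numba kernels over flat arrays; the
  readable NumPy reference implementations remain the public operations
  and the two paths are cross-checked in the test suite.

## Defaults and calibration

Defaults describe a 1 μm-diameter bead (the microspheres of the motility
assays this model emulates) in cytoplasmic extract.  Ratchet constants are
textbook: `V_max = 0.5 μm/s`, `δ = 2.7 nm`, `k_BT = 4.1e-3 pN·μm`
(`k_BT/δ ≈ 1.5 pN` per e-fold).  The mechanical and kinetic constants of
the gel are not independently measurable from the main observables, so
they were calibrated, once, to place the model in the regime the
experiments describe:

| parameter | value | role |
|---|---|---|
| `k_nuc`, `k_br` | 2.0 μm⁻¹s⁻¹, 0.2 s⁻¹ | ≈half of births per channel; ~40–60 live filaments |
| `k_att`, `k_det0`, `F_d`, `k_cap` | 0.4, 1.0 s⁻¹, 2.5 pN, 0.5 s⁻¹ | tethered-ratchet partition; attached:pushing of order one |
| `κ_f`, `κ_net` | 50, 10 pN/μm | filament vs gel compliance; `κ_net` sits in the bistable-orientation window (long-axis fraction 0.2 → 0.7 across aspect ratios 1.5 → 2.5) |
| `F_rup` | 3 pN | crosslink rupture; tail cracking at the poles is the escape path that sustains propulsion |
| `k_dis` | 0.08 s⁻¹ | node lifetime 12.5 s; treadmilling tail of a few hundred nodes |
| `μ_t`, `μ_r` | 0.025, 0.04 | overdamped, near force balance between kinetic events |
| `Δt` | 0.015 s | all tau-leap guards satisfied with margin |

Network stiffness sweeps are expressed directly in `κ_net`; the mapping to
a continuum Young's modulus would need the (unmodelled) gel microstructure
and is deliberately not reported.

Two degenerate single-mechanism presets bracket the hybrid model.
`elastic_only` (no branching, tripled uniform nucleation, attachments at a
tenth, gel stiffened to `κ_net ≥ 50` and `F_rup ≥ 10`) loads the surface
with near-uniform normal stress, and its squeezing aligns elongated beads
to travel along their long axis.  `rigid_ratchet` (gel nodes frozen at
birth, branching-dominant nucleation with faster capping) is the
microscopic rigid-array picture and drives elongated beads sideways along
their short axis, because branching concentrates pushing filaments on the
flat flank.  The full hybrid model sits between the two, which is what
produces the aspect-ratio-dependent bistability.

The pedestal force-velocity assays use their own configuration
(`experiments.fv_config`): sparser filaments (`k_nuc = 0.75`, `k_br =
0.1`, `k_att = 0.2`), a tougher network (`F_rup = 8`), slower disassembly
(`k_dis = 0.02`), and a fully equilibrated pedestal (500 sweeps, drift cap
0.2 μm/s).  Two of these choices are load-bearing: the short force-clamp
window must probe an *elastic* network (a creeping gel adds a linear
`−F/η` term that swamps the ratchet exponential), and the curve's shape is
only ratchet-dominated when stall is reached at a per-filament force
comparable to `k_BT/δ`, i.e. with few filaments sharing the load.  The
concave-down cantilever relation conversely requires the force ramp to be
slow compared with `1/k_dis`, so the loaded column ages and recoils during
the measurement — the same time-scale separation the 1D theory makes
explicit.  The surface-swap controls follow the experimental design: a
slow-growing network (halved `V_max`) against the curved cantilever, so
aging still outruns growth on the rounded contact, and a fast-growing
one against the flat force-clamped obstacle.

## The 1D aging-recoil theory

A serial chain of layers (thickness `h`, stiffness `κ0`) is deposited at
the tip at the ratchet velocity; each layer's stiffness decays as
`exp(−k_dis·age)`, so the chain compliance `C(t)` grows, and under load
`F` the obstacle velocity is `V = V_max·exp(−F·δ/k_BT) − F·k_dis·C(t)`.
Clamp mode evaluates this at a fixed age (closed form); cantilever mode
integrates the deflection ODE with `F = k_cant·x`.  With `k_dis = 0` the
clamp curve *is* the single-filament ratchet law, exactly.

## Analysis conventions

Tracks are smoothed with a five-point local cubic (Savitzky–Golay) filter,
the smoothing used on experimental bead tracks; curvature is the
central-differenced unwrapped heading rate divided by speed, masked where
the speed falls below a fraction (default 1%) of the run median, since a
stalled bead has no heading.  Trajectory ensembles are sampled at 10 s,
the cadence of the bead-tracking experiments.  Orientation classes use the
equal tri-partition of [0°, 90°] (long < 30° < skewed < 60° < short); a
run's label is its modal class over the final two thirds, skipping the
symmetry-breaking transient.  Force-velocity concavity is classified
against two templates pinned to half-maximal velocity at unit normalized
force — exponential decay vs plateau-then-crash — with a pure straight
line landing, by construction, in the indeterminate band between them.

Trajectory ensembles make two curvature reductions at different speed
conditionings: κ_rms (and the scaling rows) over samples faster than 30%
of the run-median speed, because the rms of the moving phase would
otherwise be dominated by single near-stall samples where κ = ω/v blows
up; and the pooled distribution-shape statistics over the full default
mask, because the slow-and-jagged episodes are exactly the non-Gaussian
physics those statistics detect.  The orientation crossover is the
linear interpolation of the long-axis fraction through one half, falling
back to the root of the least-squares line when no adjacent pair of
swept aspect ratios brackets it.

The curvature fluctuation model treats the bead as driven by `N` pushing
filaments with a `√N` left–right imbalance, each deflection of size the
contact angular spread `Δθ`, persisting for the filament residence time
`τ`: `κ_rms ≈ Δθ/(√N·v·τ)`.  The regression of `1/κ_rms` on
`v·τ·√N/Δθ` across runs is the package's scaling test; `Δθ` is measured
as the circular standard deviation of pushing-contact angles and `τ` as
the mean filament lifetime from birth to capping.

## Problem sizes

The bundled experiments run scaled-down ensembles — 600 s of simulated
time per run, a bead tail of a few hundred gel nodes, ensembles of 10–40
seeds per condition — which resolve the qualitative regimes (orientation
preference, curvature statistics, force-velocity shapes) with binomial or
seed-to-seed error bars that the tests account for.

## What the synthetic experiments do and do not show

The generator *is* the model: all inputs are produced by the simulator
itself, so the tests establish internal consistency of the implementation
with the model's stated mechanisms (ratchet and Bell laws at their
analytic points, master-equation occupancies, energy-minimizing gel,
treadmilling balance) and reproduction of the qualitative experimental
regimes.  They cannot validate the model against real bead tracks: 2D
dynamics (cylindrical, strictly), no excluded volume between gel and
bead, no filament orientation distribution, no membrane or myosin, no
ATP-hydrolysis aging of the gel beyond a single disassembly rate, and no
hysteresis under force.  Quantities tied to the unmodelled
microstructure — absolute Young's modulus, absolute stall forces — are
reported in model units and should be read as order-of-magnitude.

## Known limitations

* The engine-level gel is viscoelastic by construction (bounded sweep
  budget); rate-dependent phenomena faster than a few steps are not
  resolved.
* Trajectory curvature distributions carry heavy tails from slow
  episodes; the Gaussian regime is a statement about the fast-moving
  phase of motion.  Relatedly, the low-detachment regime slows smoothly
  (the drift-capped gel yields continuously) rather than pulsing between
  arrest and escape, so sustained entrapment events, in the strict
  speed-below-10%-of-median sense, are rarer here than the strongly
  pulsatory motion seen experimentally.
* The orientation bistability window in `κ_net` is finite; far outside
  it the model reduces to the degenerate single-mechanism behaviors.
* At the default density, a 600 s run takes ~10–20 s on one CPU; wall
  time grows roughly linearly in filament and node counts.
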