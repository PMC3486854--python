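# mesotail

A 2D hybrid ("mesoscopic") simulator of actin-based propulsion.  Micron
beads coated with actin nucleators — like *Listeria* and the bead-motility
assays that mimic it — are pushed by a treadmilling actin comet tail.  Two
classical pictures of this propulsion disagree: microscopic polymerization
ratchets (individual filaments pushing and tethering the surface) and
macroscopic elastic propulsion (a deformable gel squeezing a curved
obstacle forward).  `mesotail` implements both at once: the filament tips
touching the obstacle are discrete tethered-ratchet springs embedded in
the boundary of a node-spring gel that assembles at the surface, deforms
quasi-statically, and turns over by disassembly and crosslink rupture.

The model in brief (units μm, s, pN):

* free filament tips grow at the Brownian-ratchet velocity
  `V(F) = V_max·exp(−F·δ/k_BT)` and push Hookean forces `κ_f·p` along the
  surface normal for virtual penetration `p`;
* attached filaments pull through tethers and detach by Bell's law
  `k_det(F) = k_det0·exp(F/F_d)`;
* filaments nucleate spontaneously (uniform on the surface) and by
  autocatalytic branching (proportional to local filament density), cap at
  a constant rate, and mature into gel nodes;
* gel springs relax toward force balance every step, rupture above a
  critical tension `F_rup`, disassemble at rate `k_dis`, and freeze to the
  substrate far from the bead;
* the rigid elliptical bead moves and rotates overdamped under the net
  filament wrench.

On top of the simulator sit the three virtual experiments the model was
built to interrogate, with their analysis layer (Savitzky–Golay track
smoothing, trajectory curvature κ = ω/v, orientation and force-velocity
concavity classification, and the √N fluctuation-scaling regression):

| experiment | question |
|---|---|
| `orientation_assay` | do ellipsoidal beads travel along their long or short axis, as a function of aspect ratio, gel stiffness, attachment kinetics? |
| `trajectory_assay` | what do spherical-bead trajectory curvatures look like (Gaussian vs sharply peaked), and how does κ_rms scale with bead size and filament number? |
| `cantilever_fv` / `clamp_fv` / `recoil_theory_1d` | why do slow cantilever assays give concave-down force-velocity curves while fast force clamps give concave-up ones? |

## Worked example

```sh
python examples/run_single_bead.py
```

```
simulated 299 s of motion
path length      : 26.45 um
net displacement : 2.58 um  (straightness 0.10)
mean speed       : 0.088 um/s
pushing filaments: 12.4 (mean)
attached         : 13.9 (mean)
gel nodes at end : 150
```

A 1 μm bead starts with no actin at all, grows a symmetric cloud, breaks
symmetry, and crawls at ~0.1 μm/s — the speed scale of beads in
cytoplasmic extract — propelled by roughly a dozen pushing filament
clusters and held back by a comparable number of tethers, with a
treadmilling tail of ~150 gel nodes; the modest straightness reflects the
strongly fluctuating turning of small beads.  The other examples
(`orientation_of_ellipsoids.py`, `trajectory_curvature.py`,
`force_velocity.py`, `gel_mechanics.py`) each run one capability the same
way and print what the numbers mean.

A thin CLI wraps the same functions for shell use:

```sh
mesotail simulate --seed 7 --out out/            # one run, trajectory.tsv
mesotail orientation --out out/ --n-runs 20      # aspect-ratio ensemble
mesotail theory1d --mode cantilever --out out/   # 1D aging-recoil theory
```

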