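"""Virtual experiments: orientation ensembles, trajectory ensembles,
force-velocity assays, and the 1D aging-recoil theory.

Each assay runs seeded ensembles of the hybrid model and reduces them with
:mod:`mesotail.analysis`:

* :func:`orientation_assay` — sweeps the bead aspect ratio (or any other
  config axis) at constant bead area and reports the probability that runs
  end up propelled along the long axis, skewed, or along the short axis.
* :func:`trajectory_assay` — spherical-bead ensembles; per-run κ_rms,
  pooled normalized-curvature shape statistics and entrapment counts.
* :func:`cantilever_fv` / :func:`clamp_fv` — growth of an actin pedestal
  against a flat cantilever (force ∝ deflection, long measurement) or a
  force-clamped obstacle (short window at fixed network age); both support
  swapping the obstacle shape (flat ↔ round) to show the force-velocity
  concavity class is set by the actin dynamics, not the surface.
* :func:`recoil_theory_1d` — serial-spring chain deposited at the growing
  tip whose layers soften exponentially with age (disassembly); its recoil
  under load reproduces the concave-down long-time relation and reduces to
  the bare ratchet law when disassembly is off.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .analysis import ScalingRow
from .engine import SimConfig, Trajectory, run
from .filaments import polymerization_velocity
from .gel import GelNetwork

__all__ = [
    "FVCurve", "orientation_assay", "crossover_aspect_ratio",
    "trajectory_assay", "scaling_sweep", "synthetic_scaling_rows",
    "cantilever_fv", "clamp_fv", "recoil_theory_1d",
    "OrientationAssayResult", "TrajectoryAssayResult",
]


def _child_seed(seed0: int, *idx: int) -> int:
    """Deterministic per-run seed below 2**31."""
    ss = np.random.SeedSequence([int(seed0), *map(int, idx)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class FVCurve:
    """A force-velocity relation: applied force F (pN) vs measured obstacle
    velocity V (μm/s), with the assay mode and measurement window."""

    F: np.ndarray
    V: np.ndarray
    mode: str                 # "cantilever" | "clamp" | "theory1d"
    window: float = 0.0       # s

    def classify(self) -> str:
        return analysis.concavity_classify(self.F, self.V)


# ----------------------------------------------------------------------
# orientation of ellipsoidal beads

def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    p = k / n
    den = 1 + z**2 / n
    c = (p + z**2 / (2 * n)) / den
    h = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / den
    return (c - h, c + h)


@dataclass
class OrientationAssayResult:
    runs: pd.DataFrame      # one row per run: condition, seed, label
    summary: pd.DataFrame   # per condition: P(long/skewed/short) + CI on P(long)


def orientation_assay(aspect_ratios, n_runs: int, cfg: SimConfig,
                      seed0: int = 0, *, area: float | None = None,
                      sample_every: int = 5,
                      sweep_field: str | None = None,
                      sweep_values=None) -> OrientationAssayResult:
    """Ensemble probabilities of the propulsion orientation classes.

    Runs ``n_runs`` seeded simulations per condition, classifies each run by
    the modal velocity/long-axis angle class over its final two-thirds
    (:func:`mesotail.analysis.classify_orientation`), and reports class
    fractions with Wilson 95% CIs on P(long).

    By default the condition axis is the bead aspect ratio at constant bead
    area; passing ``sweep_field``/``sweep_values`` instead sweeps any other
    config field (e.g. ``kappa_net`` for network stiffness, ``k_att`` for
    the attached:pushing ratio) at fixed shape.
    """
    if area is None:
        area = math.pi * cfg.semi_axis_a * cfg.semi_axis_b
    if sweep_field is None:
        conditions = [("aspect_ratio", ar, cfg.with_aspect_ratio(ar, area))
                      for ar in aspect_ratios]
    else:
        conditions = [(sweep_field, v, cfg.replace(**{sweep_field: v}))
                      for v in sweep_values]
    rows = []
    for ci, (name, value, ccfg) in enumerate(conditions):
        for ri in range(n_runs):
            seed = _child_seed(seed0, ci, ri)
            traj = run(ccfg.replace(seed=seed))
            sub = _subsample(traj, sample_every)
            oc = analysis.classify_orientation(sub)
            rows.append({"condition": name, "value": value, "seed": seed,
                         "label": oc.label, **{f"frac_{k}": v
                                               for k, v in oc.fractions.items()}})
    runs = pd.DataFrame(rows)
    summ = []
    for (name, value), g in runs.groupby(["condition", "value"]):
        n = len(g)
        k_long = int((g.label == "long").sum())
        lo, hi = _wilson_ci(k_long, n)
        summ.append({"condition": name, "value": value, "n": n,
                     "p_long": k_long / n,
                     "p_skewed": float((g.label == "skewed").mean()),
                     "p_short": float((g.label == "short").mean()),
                     "p_long_ci_low": lo, "p_long_ci_high": hi})
    return OrientationAssayResult(runs=runs, summary=pd.DataFrame(summ))


def crossover_aspect_ratio(summary: pd.DataFrame) -> float:
    """Aspect ratio at which the preferred propulsion orientation switches:
    the balance point where P(long) = P(short).

    The balance of the two axis-aligned classes is the natural crossover
    statistic (runs in the skewed class dilute both fractions equally).
    Interpolates linearly between the two conditions whose long−short
    difference brackets zero; when no adjacent pair brackets it (small
    ensembles are noisy), falls back to the root of the least-squares line
    through all conditions, which uses every run instead of only the
    bracketing pair.
    """
    s = summary.sort_values("value")
    x = s["value"].to_numpy(float)
    y = s["p_long"].to_numpy(float) - s["p_short"].to_numpy(float)
    for i in range(len(x) - 1):
        if y[i] == 0:
            return float(x[i])
        if y[i] * y[i + 1] < 0:
            return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
    if y[-1] == 0:
        return float(x[-1])
    slope, icpt = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("the long-axis preference does not increase with "
                         "aspect ratio; no crossover to report")
    return float(-icpt / slope)


class _SubTraj:
    def __init__(self, t, x, y, theta):
        self.t, self.x, self.y, self.theta = t, x, y, theta


def _subsample(traj: Trajectory, every: int) -> _SubTraj:
    return _SubTraj(traj.t[::every], traj.x[::every], traj.y[::every],
                    traj.theta[::every])


# ----------------------------------------------------------------------
# trajectories of spherical beads

@dataclass
class TrajectoryAssayResult:
    trajectories: list
    kappa_rms: np.ndarray        # per run, μm⁻¹
    pooled_kurtosis: float       # excess kurtosis of pooled κ/κ_rms
    pooled_ks: float             # KS distance of pooled κ/κ_rms vs N(0,1)
    entrapments: np.ndarray      # events per run
    mean_speed: float            # μm/s
    mean_n_pushing: float
    rows: list = field(default_factory=list)   # ScalingRow per run

    @property
    def mean_kappa_rms(self) -> float:
        return float(np.mean(self.kappa_rms))


def trajectory_assay(n_runs: int, cfg: SimConfig, seed0: int = 0, *,
                     sample_dt: float = 10.0,
                     v_min_frac: float = 0.3) -> TrajectoryAssayResult:
    """Spherical-bead trajectory ensemble with curvature statistics.

    Tracks are subsampled to ``sample_dt`` (the cadence bead tracks are
    recorded at in the motility assays) and smoothed.  Two curvature
    reductions are made, at different speed conditionings:

    * per-run κ_rms and the fluctuation-model rows use samples with
      v ≥ ``v_min_frac`` of the run-median speed (default 30%): the
      heading of a near-stalled bead is ill-conditioned and a single
      stall sample would otherwise dominate the rms of the moving phase;
    * the pooled distribution-shape statistics (excess kurtosis, KS) keep
      every sample above the analysis default mask, because the
      slow-and-jagged episodes *are* the non-Gaussian physics the shape
      statistics are meant to detect.
    """
    if cfg.semi_axis_a != cfg.semi_axis_b:
        raise ValueError("trajectory assay expects a spherical bead (a == b)")
    every = max(int(round(sample_dt / cfg.output_every)), 1)
    trajs, krms, pooled, traps, rows, vbar, nbar = [], [], [], [], [], [], []
    for ri in range(n_runs):
        seed = _child_seed(seed0, ri)
        traj, st = run(cfg.replace(seed=seed), return_state=True)
        trajs.append(traj)
        xy = analysis.smooth_path(traj.positions[::every])
        cs = analysis.curvature_series(xy, dt=every * cfg.output_every,
                                       v_min_frac=v_min_frac)
        k = cs.kappa[cs.valid]
        r = float(np.sqrt(np.mean(k**2)))
        krms.append(r)
        cs_all = analysis.curvature_series(xy, dt=every * cfg.output_every)
        k_all = cs_all.kappa[cs_all.valid]
        pooled.append(k_all / float(np.sqrt(np.mean(k_all**2))))
        traps.append(analysis.entrapment_events(traj))
        v = float(np.nanmean(cs.v))
        vbar.append(v)
        nbar.append(float(traj.n_push.mean()))
        rows.append(ScalingRow(
            kappa_rms=r, N=max(float(traj.n_push.mean()), 1e-9),
            tau=st.fils.mean_residence_time(), dtheta=st.pushing_spread(),
            v=v, R=cfg.semi_axis_a))
    pooled = np.concatenate(pooled)
    from scipy import stats as sps

    kurt = float(sps.kurtosis(pooled, fisher=True, bias=False))
    ks = float(sps.kstest(pooled, sps.norm(loc=0, scale=pooled.std()).cdf).statistic)
    return TrajectoryAssayResult(
        trajectories=trajs, kappa_rms=np.array(krms), pooled_kurtosis=kurt,
        pooled_ks=ks, entrapments=np.array(traps),
        mean_speed=float(np.mean(vbar)), mean_n_pushing=float(np.mean(nbar)),
        rows=rows)


def scaling_sweep(cfg: SimConfig, conditions: list[dict], seeds_per: int = 1,
                  seed0: int = 0, sample_dt: float = 10.0) -> list[ScalingRow]:
    """Run one spherical-bead ensemble per condition (a dict of config
    overrides) and collect the fluctuation-model rows for
    :func:`mesotail.analysis.scaling_fit`."""
    rows = []
    for ci, kw in enumerate(conditions):
        res = trajectory_assay(seeds_per, cfg.replace(**kw),
                               seed0=_child_seed(seed0, ci),
                               sample_dt=sample_dt)
        rows.extend(res.rows)
    return rows


def synthetic_scaling_rows(n: int, slope: float, rng) -> list[ScalingRow]:
    """Rows generated exactly from the fluctuation model
    κ_rms = Δθ/(slope·√N·v·τ), for parameter-recovery checks of
    :func:`mesotail.analysis.scaling_fit`."""
    rows = []
    for _ in range(n):
        N = rng.uniform(3, 40)
        tau = rng.uniform(2, 20)
        dtheta = rng.uniform(0.3, 1.5)
        v = rng.uniform(0.02, 0.3)
        krms = dtheta / (slope * math.sqrt(N) * v * tau)
        rows.append(ScalingRow(kappa_rms=krms, N=N, tau=tau, dtheta=dtheta, v=v))
    return rows


# ----------------------------------------------------------------------
# force-velocity assays: actin pedestal against a flat or round obstacle

def fv_config(**overrides) -> SimConfig:
    """Pedestal-assay configuration: sparser surface filaments and weaker
    attachments than the bead-motility defaults, so per-filament ratchet
    mechanics (rather than force sharing across a large array) sets the
    clamp-curve shape, and slow disassembly (1/k_dis = 50 s) separates the
    short clamp window from the long cantilever ramp."""
    kw = dict(dt=0.02, kappa_net=50.0, F_rup=8.0, kappa_f=50.0,
              k_att=0.2, k_det0=1.0, F_d=2.5, k_nuc=0.75, k_br=0.1,
              mobility_t=0.025, relax_max_sweeps=500, k_dis=0.02,
              node_drift_speed=0.2)
    kw.update(overrides)
    return SimConfig(**kw)


def _triangular_pedestal(kappa_net: float, width: float = 4.0,
                         height: float = 2.0, spacing: float = 0.2) -> GelNetwork:
    """Undeformed triangular-lattice node-spring block below y = 0 with the
    bottom row immobilized (the rigid substrate)."""
    net = GelNetwork(kappa_net=kappa_net)
    dy = spacing * math.sqrt(3) / 2
    rows = max(int(round(height / dy)), 1)
    pts = []
    for r in range(rows + 1):
        y = -r * dy          # top row flush with the obstacle at y = 0
        off = 0.5 * spacing if r % 2 else 0.0
        x = -width / 2 + off
        while x <= width / 2 + 1e-9:
            pts.append((x, y, r == rows))
            x += spacing
    for (x, y, bottom) in pts:
        net.add_node((x, y), mobile=not bottom)
    # springs between lattice neighbours, at rest
    from scipy.spatial import cKDTree

    P = net.positions()
    tree = cKDTree(P)
    for i, j in sorted(tree.query_pairs(1.1 * spacing)):
        d = float(np.hypot(*(P[i] - P[j])))
        net.add_spring(i, j, rest_length=d)
    return net


class _FVState:
    """Vectorized filament/gel state for the pedestal assays.

    The obstacle is either a flat wall spanning |x| <= width/2 whose lower
    face sits at height ``y`` (outward normal (0, −1)), or a round obstacle
    of radius ``R`` centred at (0, y + R) contacted on its lower half.  It
    moves along y only.
    """

    def __init__(self, cfg: SimConfig, surface: str, width: float, R: float,
                 seed: int, pedestal_kw: dict | None = None):
        self.cfg = cfg
        self.surface = surface
        self.width = width
        self.R = R
        self.y = 0.0
        self.t = 0.0
        self.rng = np.random.default_rng(seed)
        self.net = _triangular_pedestal(cfg.kappa_net, width=width,
                                        **(pedestal_kw or {}))
        self.substrate = self.net.node_ids[~self.net.mobile[self.net.node_ids]]
        n0 = 0
        self.state = np.zeros(n0, dtype=np.int8)   # 0 free, 1 attached
        self.anchor = np.zeros(n0, dtype=np.int64)
        self.p_att = np.zeros(n0)                  # attachment param (x or angle)
        self.rest = np.zeros(n0)
        self.push_cap = 5.0 * cfg.F_rup

    # --- obstacle geometry -------------------------------------------
    def _contact(self, ax, ay):
        """Per-anchor gap to the obstacle surface and outward normal."""
        if self.surface == "flat":
            gap = self.y - ay
            nx = np.zeros_like(ax)
            ny = -np.ones_like(ax)
            param = np.clip(ax, -self.width / 2, self.width / 2)
            return gap, nx, ny, param
        cy = self.y + self.R
        dx, dy = ax, ay - cy
        r = np.hypot(dx, dy)
        r = np.maximum(r, 1e-12)
        gap = r - self.R
        return gap, dx / r, dy / r, np.arctan2(dy, dx)

    def _site(self, param):
        """World position of an attachment site."""
        if self.surface == "flat":
            return param, np.full_like(param, self.y)
        cy = self.y + self.R
        return self.R * np.cos(param), cy + self.R * np.sin(param)

    def _spawn_param_spont(self, n):
        if self.surface == "flat":
            return self.rng.uniform(-self.width / 2, self.width / 2, n)
        return self.rng.uniform(math.pi, 2 * math.pi, n)

    def _surface_extent(self) -> float:
        return self.width if self.surface == "flat" else math.pi * self.R

    # --- one step ------------------------------------------------------
    def step(self, F_ext: float):
        """Advance dt with external force F_ext (pN, along −y) on the
        obstacle; returns the net filament force on the obstacle (y)."""
        cfg = self.cfg
        dt = cfg.dt
        rng = self.rng
        # spawn: spontaneous + branching, born attached & undeformed
        n_sp = rng.poisson(cfg.k_nuc * self._surface_extent() * dt)
        n_br = rng.poisson(cfg.k_br * self.state.size * dt)
        params = list(self._spawn_param_spont(n_sp))
        if n_br and self.state.size:
            parents = rng.integers(0, self.state.size, n_br)
            ax = self.net.px[self.anchor[parents]]
            ay = self.net.py[self.anchor[parents]]
            _, _, _, pp = self._contact(ax, ay)
            off = rng.normal(0.0, cfg.sigma_br, n_br)
            if self.surface == "flat":
                params.extend(np.clip(pp + off, -self.width / 2, self.width / 2))
            else:
                params.extend(pp + off / self.R)
        for p in params:
            sx, sy = self._site(np.asarray(p, float))
            if self.surface == "flat":
                apos = (float(sx), float(sy) - cfg.L0)
            else:
                nx, ny = float(np.cos(p)), float(np.sin(p))
                apos = (float(sx) + cfg.L0 * nx, float(sy) + cfg.L0 * ny)
            aid = self.net.anchor_node(apos, cfg.anchor_radius, birth_time=self.t)
            self.state = np.append(self.state, np.int8(1))
            self.anchor = np.append(self.anchor, aid)
            self.p_att = np.append(self.p_att, float(p))
            self.rest = np.append(self.rest, cfg.L0)

        # drop filaments whose anchor was disassembled
        keep = self.net.n_alive_mask[self.anchor] if self.state.size else np.empty(0, bool)
        if self.state.size and not keep.all():
            self._filter(keep)

        ax = self.net.px[self.anchor]
        ay = self.net.py[self.anchor]
        gap, nx, ny, param = self._contact(ax, ay)
        att = self.state == 1
        sx, sy = self._site(self.p_att)
        dxs, dys = ax - sx, ay - sy
        d = np.maximum(np.hypot(dxs, dys), 1e-12)
        ext = d - self.rest
        Ft = np.where(att & (ext > 0), cfg.kappa_f * ext, 0.0)

        # transitions (tau-leap; loads from the incoming configuration)
        u = rng.random((self.state.size, 2))
        detach = att & (u[:, 0] < 1 - np.exp(-cfg.k_det0 * np.exp(Ft / cfg.F_d) * dt))
        free = ~att
        attach = free & (u[:, 0] < 1 - math.exp(-cfg.k_att * dt))
        cap = free & ~attach & (u[:, 1] < 1 - math.exp(-cfg.k_cap * dt))
        # growth of remaining free filaments under current push load
        grow = free & ~attach & ~cap
        pen = self.rest - gap
        Fp = np.clip(cfg.kappa_f * pen, 0.0, self.push_cap)
        self.rest[grow] += polymerization_velocity(
            Fp[grow], cfg.V_max, cfg.delta, cfg.kBT) * dt
        self.state[detach] = 0
        self.state[attach] = 1
        self.p_att[attach] = param[attach]
        self.rest[attach] = np.maximum(gap[attach], 1e-6)
        if cap.any():
            self._filter(~cap)
            ax, ay = self.net.px[self.anchor], self.net.py[self.anchor]
            gap, nx, ny, param = self._contact(ax, ay)

        # forces in the outgoing configuration
        att = self.state == 1
        sx, sy = self._site(self.p_att)
        dxs, dys = ax - sx, ay - sy
        d = np.maximum(np.hypot(dxs, dys), 1e-12)
        ext = np.where(att, d - self.rest, 0.0)
        Ft = np.where(ext > 0, self.cfg.kappa_f * ext, 0.0)
        pen = np.where(~att, self.rest - gap, 0.0)
        Fp = np.clip(cfg.kappa_f * pen, 0.0, self.push_cap)
        # obstacle force: pushes along -n̂, pulls toward the anchor
        fx_o = -Fp * nx + Ft * dxs / d
        fy_o = -Fp * ny + Ft * dys / d
        fxe = np.zeros_like(self.net.px)
        fye = np.zeros_like(self.net.py)
        np.add.at(fxe, self.anchor, -fx_o)
        np.add.at(fye, self.anchor, -fy_o)
        Fy = float(np.sum(fy_o))

        self.net.relax((fxe, fye), tol=cfg.relax_tol,
                       max_sweeps=cfg.relax_max_sweeps,
                       damping=cfg.relax_damping,
                       max_shift=cfg.node_drift_speed * dt)
        # obstacle motion along y under filament + external force
        self.y += cfg.mobility_t * (Fy - F_ext) * dt
        self.net.rupture(cfg.F_rup)
        self.net.disassemble(cfg.k_dis, dt, rng, protect=self.substrate)
        self.t += dt
        return Fy

    def _filter(self, keep):
        self.state = self.state[keep]
        self.anchor = self.anchor[keep]
        self.p_att = self.p_att[keep]
        self.rest = self.rest[keep]


def cantilever_fv(k_cant: float, T: float, cfg: SimConfig, *,
                  surface: str = "flat", width: float = 4.0, R: float = 1.5,
                  seed: int = 0, sample_window: float = 20.0,
                  n_seeds: int = 1) -> FVCurve:
    """Growth against an elastic cantilever: the opposing force is
    k_cant × cumulative deflection, so force ramps as the pedestal grows
    and the network ages during the measurement.  Velocities are windowed
    displacement increments; the curve runs from free growth to stall.
    With ``n_seeds`` > 1 the deflection history is averaged over replicate
    runs before differencing (the stochastic velocity signal is noisy on
    the window scale).
    """
    n = int(round(T / cfg.dt))
    m = max(int(round(sample_window / cfg.dt)), 1)
    all_ys = []
    for r in range(n_seeds):
        sim = _FVState(cfg, surface, width, R, _child_seed(seed, r))
        ys, ts = [sim.y], [0.0]
        for k in range(n):
            sim.step(F_ext=k_cant * max(sim.y, 0.0))
            if (k + 1) % m == 0:
                ys.append(sim.y)
                ts.append(sim.t)
        all_ys.append(ys)
    ys = np.mean(all_ys, axis=0)
    ts = np.asarray(ts)
    V = np.diff(ys) / np.diff(ts)
    F = k_cant * np.maximum(0.5 * (ys[1:] + ys[:-1]), 0.0)
    return FVCurve(F=F, V=np.maximum(V, 0.0), mode="cantilever",
                   window=sample_window)


def default_clamp_forces(cfg: SimConfig) -> list[float]:
    """Clamp-force ladder spanning free growth to near stall for the
    pedestal assay defaults."""
    return [0.0, 0.4, 0.8, 1.2, 1.7, 2.2, 2.8, 3.5, 4.5, 6.0]


def clamp_fv(forces, window: float, cfg: SimConfig, *,
             surface: str = "round", width: float = 4.0, R: float = 1.5,
             seed: int = 0, T_grow: float = 40.0,
             n_seeds: int = 1) -> FVCurve:
    """Force-clamp assay: a pedestal-plus-tail is grown unloaded to a fixed
    age, then each clamped force is applied to an identical copy of that
    state for a short ``window`` (short relative to 1/k_dis, so the network
    does not disassemble significantly during the measurement) and the mean
    velocity is recorded, averaged over ``n_seeds`` replicate growths."""
    V = np.zeros(len(forces))
    n = int(round(window / cfg.dt))
    for r in range(n_seeds):
        base = _FVState(cfg, surface, width, R, _child_seed(seed, r))
        for _ in range(int(round(T_grow / cfg.dt))):
            base.step(F_ext=0.0)
        for j, F in enumerate(forces):
            sim = copy.deepcopy(base)
            y0 = sim.y
            for _ in range(n):
                sim.step(F_ext=float(F))
            V[j] += (sim.y - y0) / window
    V /= n_seeds
    return FVCurve(F=np.asarray(forces, float), V=np.maximum(V, 0.0),
                   mode="clamp", window=window)


# ----------------------------------------------------------------------
# 1D aging-recoil theory

def recoil_theory_1d(*, V_max: float = 0.5, delta: float = 0.0027,
                     kBT: float = 0.0041, k_dis: float = 0.01,
                     kappa_layer: float = 50.0, layer_h: float = 0.2,
                     mode: str = "clamp", forces=None, age: float = 60.0,
                     k_cant: float = 0.05, T: float = 4000.0,
                     dt: float = 0.05) -> FVCurve:
    """Serial-chain theory of a growing, disassembling 1D network.

    Layers of thickness ``layer_h`` and stiffness ``kappa_layer`` are
    deposited at the tip at the ratchet velocity; each layer's stiffness
    decays as exp(−k_dis·age) as the network disassembles, so the chain's
    total compliance C grows with time.  Under load F the aged chain
    recoils at rate F·k_dis·C, and the obstacle velocity is

        V(F) = V_max·exp(−F·δ/k_BT) − F·k_dis·C(t).

    ``clamp`` mode evaluates this at a fixed network ``age`` (grown
    unloaded) for each clamped force — with k_dis = 0 it reduces exactly to
    the single-filament ratchet law.  ``cantilever`` mode integrates the
    deflection ODE with F = k_cant·x while the network keeps aging, which
    drives the rapid downturn and finite stall of the long-time assay.
    """
    def v_p(F):
        return polymerization_velocity(F, V_max, delta, kBT)

    if mode == "clamp":
        if forces is None:
            forces = np.linspace(0.0, 3.0 * kBT / delta, 13)
        forces = np.asarray(forces, float)
        v0 = v_p(0.0)
        if k_dis > 0:
            C = v0 / (layer_h * kappa_layer * k_dis) * math.expm1(k_dis * age)
        else:
            C = v0 * age / (layer_h * kappa_layer)
        V = v_p(forces) - forces * k_dis * C
        return FVCurve(F=forces, V=np.maximum(V, 0.0), mode="theory1d",
                       window=age)
    if mode != "cantilever":
        raise ValueError("mode must be 'clamp' or 'cantilever'")
    x = 0.0
    C = 0.0
    out_F, out_V = [], []
    n = int(round(T / dt))
    for k in range(n):
        F = k_cant * x
        V = v_p(F) - F * k_dis * C
        x += V * dt
        C += (k_dis * C + v_p(F) / (layer_h * kappa_layer)) * dt
        out_F.append(F)
        out_V.append(max(V, 0.0))
        if V < 1e-4 * V_max:
            break
    # thin to a manageable curve
    take = np.unique(np.linspace(0, len(out_F) - 1, 60).astype(int))
    return FVCurve(F=np.asarray(out_F)[take], V=np.asarray(out_V)[take],
                   mode="theory1d", window=T)
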