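"""Time-stepping loop: configuration, state, trajectory output.

One step of the hybrid model applies, in order: (1) filament nucleation and
branching, (2) filament state transitions and ratchet growth, (3) filament
force summation, (4) quasi-static gel relaxation with the filament reactions
as external forces, (5) overdamped bead pose update, (6) crosslink rupture,
(7) bulk disassembly, (8) far-field freezing.  Kinetics are tau-leaped with
per-event Bernoulli/Poisson draws on a fixed Δt; mechanics relax after the
kinetics, so the network deforms in response to the forces the filaments
exert in the updated configuration.

A fixed seed gives a bit-identical run: a single RNG stream drives all
stochastic events and every container iterates in id order.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .bead_dynamics import StepSizeError, Wrench, advance_bead
from .filaments import FilamentSystem, KineticRates, spawn_filaments, update_filament_states
from .gel import GelNetwork
from .geometry import Bead

__all__ = ["SimConfig", "SimState", "Trajectory", "init_state", "step", "run"]

MODES = ("full_hybrid", "elastic_only", "rigid_ratchet")


@dataclass
class SimConfig:
    """Every rate, mechanical constant, geometric length and numeric control
    of a run, with a single RNG seed.

    Defaults are the package's standard conditions: a 1 μm-radius bead
    propelled by a treadmilling tail of a few hundred gel nodes and a few
    tens of surface filaments.  Units: μm, s, pN.
    """

    # geometry: a 1 μm-diameter bead, the scale of the motility assays
    semi_axis_a: float = 0.5
    semi_axis_b: float = 0.5
    anchor_radius: float = 0.3
    d_freeze: float = 1.5
    sigma_br: float = 0.1
    L0: float = 0.05

    # filament kinetics (roughly half of births come from each nucleation
    # channel at the steady-state filament count)
    k_nuc: float = 2.0     # μm⁻¹ s⁻¹ along the surface
    k_br: float = 0.2      # s⁻¹ per filament
    k_att: float = 0.4     # s⁻¹
    k_det0: float = 1.0    # s⁻¹
    F_d: float = 2.5       # pN
    k_cap: float = 0.5     # s⁻¹

    # mechanics
    kappa_f: float = 50.0    # pN/μm filament stiffness
    kappa_net: float = 10.0  # pN/μm gel spring stiffness
    F_rup: float = 3.0       # pN crosslink rupture force
    k_dis: float = 0.08      # s⁻¹ per node bulk disassembly
    V_max: float = 0.5       # μm/s unloaded polymerization velocity
    delta: float = 0.0027    # μm ratchet step (half a monomer, 2D convention)
    kBT: float = 0.0041      # pN·μm
    mobility_t: float = 0.025  # μm s⁻¹ pN⁻¹
    mobility_r: float = 0.04   # rad s⁻¹ (pN μm)⁻¹

    # numerics
    dt: float = 0.015
    relax_tol: float = 1e-2
    relax_max_sweeps: int = 30
    relax_damping: float = 0.8
    node_drift_speed: float = 3.0  # μm/s cap on per-node motion during relax
    seed: int = 0
    T_end: float = 600.0
    output_every: float = 1.0
    mode: str = "full_hybrid"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.semi_axis_a < self.semi_axis_b:
            raise ValueError("semi_axis_a must be >= semi_axis_b")
        # tau-leap guards
        fastest = max(self.k_att, self.k_det0, self.k_cap)
        if fastest * self.dt >= 0.2:
            raise ValueError("dt too large for the fastest kinetic rate (rate*dt < 0.2)")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def with_aspect_ratio(self, aspect: float, area: float | None = None) -> "SimConfig":
        """Same config with the bead reshaped to ``aspect`` at constant area."""
        if area is None:
            area = math.pi * self.semi_axis_a * self.semi_axis_b
        b = math.sqrt(area / (math.pi * aspect))
        return self.replace(semi_axis_a=aspect * b, semi_axis_b=b)

    def resolved(self) -> "SimConfig":
        """Apply the mode presets.

        * ``elastic_only`` — the degenerate macroscopic model: branching off
          and attachments weakened, so the gel exerts near-uniform normal
          stress and propulsion is purely elastic squeezing.
        * ``rigid_ratchet`` — the degenerate microscopic model: every gel
          node freezes at birth, so filaments push/pull from rigid anchors
          and the gel never deforms.
        """
        if self.mode == "elastic_only":
            # no branching; dense uniform spontaneous nucleation and weak
            # attachments, on a stiff tough gel: the network loads the
            # surface with near-uniform normal stress and its squeezing
            # dominates the dynamics
            return self.replace(k_br=0.0, k_nuc=3.0 * self.k_nuc,
                                k_att=0.1 * self.k_att,
                                kappa_net=max(self.kappa_net, 50.0),
                                F_rup=max(self.F_rup, 10.0))
        if self.mode == "rigid_ratchet":
            # branching-dominant nucleation with fast capping: the
            # microscopic picture of a rigid dendritic array pushing the
            # bead, with no gel compliance (nodes freeze at birth)
            return self.replace(k_nuc=0.25 * self.k_nuc,
                                k_br=1.5 * self.k_br,
                                k_cap=2.0 * self.k_cap)
        return self

    @property
    def freeze_at_birth(self) -> bool:
        return self.mode == "rigid_ratchet"

    def rates(self) -> KineticRates:
        c = self.resolved()
        return KineticRates(k_nuc=c.k_nuc, k_br=c.k_br, k_att=c.k_att,
                            k_det0=c.k_det0, F_d=c.F_d, k_cap=c.k_cap)


@dataclass
class SimState:
    bead: Bead
    net: GelNetwork
    fils: FilamentSystem
    t: float = 0.0
    rng: np.random.Generator = None
    events: dict = field(default_factory=lambda: {
        "births": 0, "cappings": 0, "ruptures": 0, "removals": 0,
        "relax_fail": 0})
    last_wrench: Wrench = field(default_factory=Wrench)
    last_counts: tuple = (0, 0)
    # accumulators for the pushing-contact circular spread (Δθ)
    _R_sum: float = 0.0
    _R_n: int = 0

    def pushing_spread(self) -> float:
        """Circular standard deviation (rad) of the world angles of the
        pushing contact points about the bead center, averaged over steps —
        the Δθ of the curvature fluctuation model."""
        if self._R_n == 0:
            return float("nan")
        Rbar = min(max(self._R_sum / self._R_n, 1e-12), 1.0 - 1e-12)
        return math.sqrt(-2.0 * math.log(Rbar))


class Trajectory:
    """Time series of bead pose plus per-step diagnostics.

    Columns: t, x, y, theta, n_push, n_att, n_nodes, fx, fy, torque.
    """

    _cols = ("t", "x", "y", "theta", "n_push", "n_att", "n_nodes",
             "fx", "fy", "torque")

    def __init__(self):
        self._rows = []

    def append(self, *row):
        self._rows.append(row)

    def __len__(self):
        return len(self._rows)

    def __getattr__(self, name):
        if name in self._cols:
            arr = np.asarray(self._rows, dtype=float)
            if arr.size == 0:
                return np.empty(0)
            return arr[:, self._cols.index(name)]
        raise AttributeError(name)

    @property
    def positions(self) -> np.ndarray:
        arr = np.asarray(self._rows, dtype=float)
        return arr[:, 1:3] if arr.size else np.empty((0, 2))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self._rows, columns=self._cols)

    def write(self, path):
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path):
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        tr = cls()
        for row in df[list(cls._cols)].itertuples(index=False):
            tr.append(*row)
        return tr


def init_state(cfg: SimConfig) -> SimState:
    bead = Bead(cfg.semi_axis_a, cfg.semi_axis_b,
                mobility_t=cfg.mobility_t, mobility_r=cfg.mobility_r)
    net = GelNetwork(kappa_net=cfg.kappa_net)
    fils = FilamentSystem(kappa_f=cfg.kappa_f, push_cap=5.0 * cfg.F_rup)
    rng = np.random.default_rng(cfg.seed)
    return SimState(bead=bead, net=net, fils=fils, rng=rng)


def step(state: SimState, cfg: SimConfig) -> SimState:
    """Advance the state by exactly one Δt (see module docstring for the
    sub-update order)."""
    return _step(state, cfg, cfg.resolved(), cfg.rates())


def _step(state: SimState, cfg: SimConfig, c: SimConfig,
          rates: KineticRates) -> SimState:
    bead, net, fils, rng = state.bead, state.net, state.fils, state.rng

    if fils.n > 5000:
        raise RuntimeError(
            f"filament population diverged ({fils.n} live at t={state.t:.1f} s): "
            "autocatalytic branching gain k_br x lifetime exceeds 1; "
            f"events so far: {state.events}")

    # (1) nucleation + branching
    new = spawn_filaments(fils, bead, net, rates, c.dt, rng,
                          L0=c.L0, sigma_br=c.sigma_br,
                          anchor_radius=c.anchor_radius, now=state.t,
                          anchor_mobile=not cfg.freeze_at_birth)
    state.events["births"] += len(new)

    # drop filaments whose anchor node was disassembled
    fidx = fils.ids
    if fidx.size:
        dead = fidx[~net.n_alive_mask[fils.anchor[fidx]]]
        for i in dead:
            fils.remove(i, now=state.t)

    # (2)+(3) filament kinetics, growth and forces
    F, T, fext, diag = update_filament_states(
        fils, bead, net, rates, c.dt, rng,
        V_max=c.V_max, delta=c.delta, kBT=c.kBT, now=state.t)
    state.events["cappings"] += diag.get("n_capped", 0)
    state.last_wrench = Wrench(F, T)
    state.last_counts = (diag["n_push"], diag["n_att"])
    if diag["n_push"] > 1:
        state._R_sum += math.hypot(diag["res_c"], diag["res_s"]) / diag["n_push"]
        state._R_n += 1

    # (4) quasi-static gel relaxation under the filament reactions
    _relax_with_reactions(state, c, fext)

    # (5) overdamped bead motion; rare force spikes (rupture cascades,
    # heavily loaded tethers) are integrated with force-recomputing
    # substeps instead of one oversized jump
    try:
        advance_bead(bead, state.last_wrench, c.dt)
    except StepSizeError:
        state.events["substeps"] = state.events.get("substeps", 0) + 1
        _advance_substepped(state, c, rates)

    # (6) crosslink rupture, (7) bulk disassembly, (8) far-field freezing
    nidx = net.node_ids
    u = rng.random(nidx.size)
    p_rem = -math.expm1(-c.k_dis * c.dt)
    n_rupt, n_rem, _ = _kernels.maintenance_pass(
        net.px, net.py, net.si, net.sj, net.s_rest, net.s_kappa,
        net.spring_ids, net.s_alive, net.n_alive_mask, net._deg, nidx,
        u, p_rem, c.F_rup, net.mobile,
        bead.center[0], bead.center[1], bead.orientation,
        bead.semi_axis_a, bead.semi_axis_b, c.d_freeze,
        not cfg.freeze_at_birth)
    if n_rupt or n_rem:
        net._invalidate()
    state.events["ruptures"] += n_rupt
    state.events["removals"] += n_rem

    state.t += c.dt
    return state


def _relax_with_reactions(state: SimState, c: SimConfig, fext):
    if c.mode == "rigid_ratchet":
        return
    net = state.net
    net.spring_ids  # refresh stiffness sums
    # isolated mobile anchors (no springs yet) have no elastic environment:
    # they yield against the filament's own stiffness instead of pinning
    fxe, fye = fext
    iso = net.node_ids[(net._stiffsum[net.node_ids] == 0.0)
                       & net.mobile[net.node_ids]]
    if iso.size:
        net.px[iso] += fxe[iso] / c.kappa_f
        net.py[iso] += fye[iso] / c.kappa_f
    res = net.relax(fext, tol=c.relax_tol, max_sweeps=c.relax_max_sweeps,
                    damping=c.relax_damping,
                    max_shift=c.node_drift_speed * c.dt)
    if not res.converged:
        state.events["relax_fail"] += 1


def _advance_substepped(state: SimState, c: SimConfig, rates: KineticRates,
                        n_sub: int = 8):
    """Integrate one Δt of bead motion in ``n_sub`` substeps, recomputing
    filament forces and relaxing the gel in between (no kinetic draws, so
    the RNG stream is untouched)."""
    dt_sub = c.dt / n_sub
    for _ in range(n_sub):
        F, T, fext, diag = update_filament_states(
            state.fils, state.bead, state.net, rates, dt_sub, state.rng,
            V_max=c.V_max, delta=c.delta, kBT=c.kBT, now=state.t,
            kinetics=False)
        state.last_wrench = Wrench(F, T)
        state.last_counts = (diag["n_push"], diag["n_att"])
        _relax_with_reactions(state, c, fext)
        dx = state.bead.mobility_t * F * dt_sub
        # saturate at the guard displacement rather than aborting the run
        nrm = float(np.hypot(*dx))
        cap = 0.1 * state.bead.semi_axis_b
        if nrm > cap:
            dx *= cap / nrm
        state.bead.center = state.bead.center + dx
        state.bead.orientation = float(
            state.bead.orientation + state.bead.mobility_r * T * dt_sub)


def run(cfg: SimConfig, snapshot_dir: str | Path | None = None,
        return_state: bool = False):
    """Run the model to ``T_end``, recording trajectory rows (and optional
    gel/filament snapshot tables) at the output cadence.  With
    ``return_state`` the final :class:`SimState` is returned alongside the
    trajectory (for turnover-time and contact-spread diagnostics)."""
    state = init_state(cfg)
    traj = Trajectory()
    n_steps = int(round(cfg.T_end / cfg.dt))
    rec_every = max(int(round(cfg.output_every / cfg.dt)), 1)
    if snapshot_dir is not None:
        snapshot_dir = Path(snapshot_dir)
        snapshot_dir.mkdir(parents=True, exist_ok=True)
        _write_snapshot(snapshot_dir, state, 0)

    def record():
        traj.append(state.t, state.bead.center[0], state.bead.center[1],
                    state.bead.orientation,
                    state.last_counts[0], state.last_counts[1],
                    state.net.n_nodes,
                    state.last_wrench.force[0], state.last_wrench.force[1],
                    state.last_wrench.torque)

    record()
    frame = 1
    c = cfg.resolved()
    rates = cfg.rates()
    for k in range(n_steps):
        _step(state, cfg, c, rates)
        if (k + 1) % rec_every == 0:
            record()
            if snapshot_dir is not None:
                _write_snapshot(snapshot_dir, state, frame)
                frame += 1
    if return_state:
        return traj, state
    return traj


def _write_snapshot(outdir: Path, state: SimState, frame: int):
    state.net.node_table().to_csv(outdir / f"nodes_{frame:05d}.tsv", sep="\t", index=False)
    state.net.spring_table().to_csv(outdir / f"springs_{frame:05d}.tsv", sep="\t", index=False)
    import pandas as pd

    ids = state.fils.ids
    pd.DataFrame({
        "state": np.where(state.fils.state[ids] == 1, "attached", "free"),
        "anchor": state.fils.anchor[ids],
        "contact_param": state.fils.t_contact[ids],
        "rest_length": state.fils.rest[ids],
    }).to_csv(outdir / f"filaments_{frame:05d}.tsv", sep="\t", index=False)
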