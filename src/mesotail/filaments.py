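"""Discrete surface filaments: tethered-ratchet kinetics and forces.

Each :class:`Filament` stands for a small cluster of actin filaments whose
barbed ends interact directly with the obstacle surface.  A filament is born
attached and undeformed, its pointed end anchored as a new gel node.  It then
cycles between two states:

* **attached** — a tether to a fixed body-frame site on the surface.  When
  stretched it pulls the obstacle back with Hookean force κ_f·(d − rest) and
  detaches with the Bell-law rate k_det0·exp(F/F_d).
* **free** — a growing rod from the anchor toward the surface.  Its rest
  length elongates at the Brownian-ratchet velocity
  V_max·exp(−F·δ/k_BT) under its current compressive load; whenever the
  rest-length tip would overlap the bead, the virtual penetration depth p
  converts to a push κ_f·p perpendicular to the surface.  Free filaments
  re-attach (rate k_att) or get capped (rate k_cap); capping deletes the
  filament but leaves its anchor node in the gel, which is how surface actin
  matures into bulk gel.

New filaments appear by spontaneous nucleation (uniform per unit arclength)
and by autocatalytic branching (proportional to the number of existing
filaments, placed near a parent's contact point) — the dendritic-nucleation
picture coarse-grained to the surface.

Every force on the bead has an exact opposite reaction on the filament's
anchor node; that reaction is what deforms the gel.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import ATTACHED, FREE
from .gel import GelNetwork
from .geometry import Bead, nearest_surface, outward_normal, surface_point

__all__ = [
    "KineticRates",
    "Filament",
    "FilamentSystem",
    "detachment_rate",
    "polymerization_velocity",
    "filament_force",
    "spawn_filaments",
    "update_filament_states",
]


@dataclass
class KineticRates:
    """Kinetic constants of the surface-filament life cycle.

    k_nuc : spontaneous nucleation, μm⁻¹·s⁻¹ of surface arclength
    k_br  : autocatalytic branching, s⁻¹ per existing filament
    k_att : re-attachment of free filaments, s⁻¹
    k_det0: unloaded detachment, s⁻¹
    F_d   : detachment force scale (Bell law), pN
    k_cap : capping, s⁻¹
    """

    k_nuc: float = 0.3
    k_br: float = 0.05
    k_att: float = 1.0
    k_det0: float = 0.5
    F_d: float = 2.0
    k_cap: float = 0.5

    def __post_init__(self):
        for f in ("k_nuc", "k_br", "k_att", "k_det0", "k_cap"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def detachment_rate(F: float, k_det0: float, F_d: float):
    """Bell's law: attachment dissociation rate k_det0·exp(F/F_d) under
    tensile load F (pN)."""
    if F_d <= 0:
        raise ValueError("F_d must be > 0")
    return k_det0 * np.exp(np.asarray(F, float) / F_d)


def polymerization_velocity(F: float, V_max: float, delta: float, kBT: float):
    """Brownian-ratchet elongation velocity V_max·exp(−F·δ/k_BT) of a free
    filament under compressive load F (pN); δ in μm, k_BT in pN·μm."""
    return V_max * np.exp(-np.asarray(F, float) * delta / kBT)


@dataclass
class Filament:
    """Read-only view of one filament (see :class:`FilamentSystem`)."""

    state: str
    anchor_node: int
    contact_param: float
    rest_length: float
    birth_time: float
    attach_param: float | None = None


class FilamentSystem:
    """Struct-of-arrays container for the live filaments.

    ``kappa_f`` (pN/μm) is the elastic stiffness of a filament treated as a
    linear spring, shared by the pushing and pulling channels; ``push_cap``
    saturates the penetration force on rare deep-overlap events to keep the
    explicit scheme stable (numerical safety, not physics).
    """

    def __init__(self, kappa_f: float = 100.0, push_cap: float = math.inf):
        self.kappa_f = float(kappa_f)
        self.push_cap = float(push_cap)
        n0 = 256
        self.state = np.zeros(n0, dtype=np.int8)
        self.anchor = np.zeros(n0, dtype=np.int64)
        self.t_att = np.zeros(n0)
        self.rest = np.zeros(n0)
        self.t_contact = np.zeros(n0)
        self.birth = np.zeros(n0)
        self.alive = np.zeros(n0, dtype=bool)
        self.n_top = 0
        self._fidx = None
        # residence-time bookkeeping for the network-turnover estimate
        self.lifetime_sum = 0.0
        self.lifetime_n = 0

    def _grow(self):
        for name in ("state", "anchor", "t_att", "rest", "t_contact", "birth", "alive"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros_like(arr)]))

    @property
    def ids(self) -> np.ndarray:
        if self._fidx is None:
            self._fidx = np.flatnonzero(self.alive[: self.n_top])
        return self._fidx

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def counts(self) -> tuple[int, int]:
        """(n_attached, n_free) over live filaments."""
        ids = self.ids
        n_att = int(np.sum(self.state[ids] == ATTACHED))
        return n_att, int(ids.size) - n_att

    def add(self, t_param: float, anchor_id: int, rest_length: float,
            birth_time: float = 0.0, attached: bool = True) -> int:
        if rest_length <= 0:
            raise ValueError("rest_length must be > 0")
        if self.n_top == self.state.size:
            self._grow()
        i = self.n_top
        self.state[i] = ATTACHED if attached else FREE
        self.anchor[i] = anchor_id
        self.t_att[i] = t_param
        self.t_contact[i] = t_param
        self.rest[i] = rest_length
        self.birth[i] = birth_time
        self.alive[i] = True
        self.n_top += 1
        self._fidx = None
        return i

    def remove(self, i: int, now: float | None = None):
        self.alive[i] = False
        self._fidx = None
        if now is not None:
            self.lifetime_sum += now - self.birth[i]
            self.lifetime_n += 1

    def view(self, i: int) -> Filament:
        return Filament(
            state="attached" if self.state[i] == ATTACHED else "free",
            anchor_node=int(self.anchor[i]),
            contact_param=float(self.t_contact[i]),
            rest_length=float(self.rest[i]),
            birth_time=float(self.birth[i]),
            attach_param=float(self.t_att[i]) if self.state[i] == ATTACHED else None,
        )

    def mean_residence_time(self) -> float:
        """Mean filament lifetime from birth to capping/removal, s — the
        surface-layer turnover time used by the curvature scaling model."""
        return self.lifetime_sum / max(self.lifetime_n, 1)


def filament_force(fils: FilamentSystem, i: int, bead: Bead, net: GelNetwork):
    """Force of filament ``i`` on the bead and the equal-and-opposite
    reaction on its anchor node.

    Free filament: the barbed end sits ``rest_length`` along the line from
    the anchor toward its nearest surface point; if it overlaps the bead by
    p > 0 the bead is pushed by κ_f·p along the inward normal at that point
    (i.e. away from the anchor).  Attached filament: Hookean pull toward the
    anchor applied at the attachment site when stretched; tethers transmit
    tension only.  Returns ``(force_on_bead, reaction, application_point)``.
    """
    A = np.array([net.px[fils.anchor[i]], net.py[fils.anchor[i]]])
    if fils.state[i] == ATTACHED:
        S = surface_point(bead, fils.t_att[i])
        d = float(np.hypot(*(A - S)))
        ext = d - fils.rest[i]
        if ext > 0 and d > 1e-12:
            f = fils.kappa_f * ext * (A - S) / d
        else:
            f = np.zeros(2)
        return f, -f, S
    q, _, gap = nearest_surface(bead, A)
    pen = fils.rest[i] - gap
    if pen <= 0:
        return np.zeros(2), np.zeros(2), q
    _, t, _ = nearest_surface(bead, A)
    n_hat = outward_normal(bead, t)
    Fp = min(fils.kappa_f * pen, fils.push_cap)
    f = -Fp * n_hat
    return f, -f, q


def spawn_filaments(fils: FilamentSystem, bead: Bead, net: GelNetwork,
                    rates: KineticRates, dt: float, rng,
                    *, L0: float = 0.05, sigma_br: float = 0.1,
                    anchor_radius: float = 0.3, now: float = 0.0,
                    anchor_mobile: bool = True) -> list[int]:
    """Create new filaments over one time step.

    Spontaneous births are uniform in surface arclength with total mean
    k_nuc·perimeter·dt; branching births have total mean k_br·N·dt, each
    placed at a parent's contact point plus a Gaussian arclength offset of
    width ``sigma_br`` (the branching locality that lets actin spread along
    flat surface regions).  Every newborn is attached and undeformed with
    rest length ``L0``, its pointed end anchored into the gel at L0 outside
    the surface.  Returns the new filament ids.
    """
    n_sp = rng.poisson(rates.k_nuc * bead.perimeter * dt)
    n_br = rng.poisson(rates.k_br * fils.n * dt) if fils.n else 0
    new = []
    if n_sp == 0 and n_br == 0:
        return new
    params = []
    if n_sp:
        s = rng.random(n_sp) * bead.perimeter
        params.extend(bead.param_at_arclength(s))
    if n_br:
        ids = fils.ids
        parents = ids[rng.integers(0, ids.size, n_br)]
        for p in parents:
            s0 = bead.arclength_of_param(fils.t_contact[p])
            params.append(float(bead.param_at_arclength(s0 + rng.normal(0.0, sigma_br))))
    for t in params:
        q = surface_point(bead, t)
        n_hat = outward_normal(bead, t)
        a_id = net.anchor_node(q + L0 * n_hat, anchor_radius,
                               mobile=anchor_mobile, birth_time=now)
        new.append(fils.add(t, a_id, L0, birth_time=now, attached=True))
    return new


def update_filament_states(fils: FilamentSystem, bead: Bead, net: GelNetwork,
                           rates: KineticRates, dt: float, rng,
                           *, V_max: float = 0.5, delta: float = 0.0027,
                           kBT: float = 0.0041, now: float = 0.0,
                           kinetics: bool = True):
    """Tau-leap all filament state transitions and growth for one step and
    accumulate the resulting forces.

    Wraps the fused kernel: per filament the transition probabilities use
    the load of the incoming configuration; pushes/pulls of the outgoing
    configuration are summed into the bead wrench and into per-node reaction
    forces.  Returns ``(wrench_force, wrench_torque, fext, diag)`` where
    ``fext`` is the (fx, fy) per-node reaction pair for the gel relaxation
    and ``diag`` carries (n_push, n_att, contact-direction resultant).
    """
    fidx = fils.ids
    fxe = np.zeros_like(net.px)
    fye = np.zeros_like(net.py)
    if fidx.size == 0:
        return np.zeros(2), 0.0, (fxe, fye), {"n_push": 0, "n_att": 0,
                                              "res_c": 0.0, "res_s": 0.0}
    u = rng.random((fidx.size, 2)) if kinetics else np.zeros((fidx.size, 2))
    removed = np.zeros(fidx.size, dtype=np.uint8)
    Fx, Fy, Tq, n_push, n_att, sc, ss = _kernels.filament_pass(
        fidx, fils.state, fils.anchor, fils.t_att, fils.rest, fils.t_contact,
        net.px, net.py,
        bead.center[0], bead.center[1], bead.orientation,
        bead.semi_axis_a, bead.semi_axis_b,
        fils.kappa_f, fils.push_cap,
        rates.k_det0, rates.F_d, rates.k_att, rates.k_cap,
        V_max, delta / kBT, dt,
        u, removed, fxe, fye, kinetics,
    )
    capped = fidx[removed == 1]
    for i in capped:
        fils.remove(i, now=now)  # anchor node persists in the gel
    return (np.array([Fx, Fy]), float(Tq), (fxe, fye),
            {"n_push": int(n_push), "n_att": int(n_att),
             "res_c": float(sc), "res_s": float(ss), "n_capped": int(capped.size)})
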