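"""Node-spring representation of the bulk actin gel.

Actin that is no longer in direct contact with the propelled surface is
coarse-grained into a network of nodes joined by Hookean springs.  The
network is built incrementally — every new filament anchors its pointed end
as a fresh node, linked by undeformed springs to up to four nearby nodes —
and destroyed incrementally by stochastic node removal (bulk disassembly)
and by rupture of springs stretched beyond a critical tension.  Between
kinetic events the network is quasi-static: nodes are swept toward force
equilibrium by a damped Jacobi relaxation.  Nodes far behind the moving
surface freeze in place, emulating adhesion of the aged tail to the
substrate; freezing is irreversible.

Storage is struct-of-arrays with ``alive`` masks and capacity doubling;
node/spring ids are stable array indices, which makes runs bit-reproducible
for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import Bead

__all__ = ["GelNetwork", "RelaxResult", "RelaxationError"]


class RelaxationError(RuntimeError):
    """Raised by strict relaxation when the residual tolerance is not met."""

    def __init__(self, residual, tol, sweeps):
        super().__init__(
            f"relaxation did not converge: residual {residual:.3g} pN "
            f"> tol {tol:.3g} pN after {sweeps} sweeps"
        )
        self.residual = residual
        self.tol = tol
        self.sweeps = sweeps


@dataclass
class RelaxResult:
    residual: float  # max |net force| on a movable connected node, pN
    sweeps: int
    converged: bool


class GelNetwork:
    """Mobile/frozen nodes connected by rupturable Hookean springs."""

    def __init__(self, kappa_net: float = 25.0):
        self.kappa_net = float(kappa_net)
        n0, s0 = 256, 1024
        self.px = np.zeros(n0)
        self.py = np.zeros(n0)
        self.mobile = np.zeros(n0, dtype=bool)
        self.n_alive_mask = np.zeros(n0, dtype=bool)
        self.birth = np.zeros(n0)
        self.n_top = 0
        self.si = np.zeros(s0, dtype=np.int64)
        self.sj = np.zeros(s0, dtype=np.int64)
        self.s_rest = np.zeros(s0)
        self.s_kappa = np.zeros(s0)
        self.s_alive = np.zeros(s0, dtype=bool)
        self.s_top = 0
        self._stiffsum = np.zeros(n0)
        self._fx = np.zeros(n0)
        self._fy = np.zeros(n0)
        self._ox = np.zeros(n0)
        self._oy = np.zeros(n0)
        self._nidx = None   # cached live node index
        self._sidx = None   # cached live spring index
        # per-node incident live-spring count, for O(1) cascade removal
        self._deg = np.zeros(n0, dtype=np.int64)

    # ------------------------------------------------------------------
    # bookkeeping
    def _grow_nodes(self):
        for name in ("px", "py", "mobile", "n_alive_mask", "birth",
                     "_stiffsum", "_fx", "_fy", "_ox", "_oy", "_deg"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros_like(arr)]))

    def _grow_springs(self):
        for name in ("si", "sj", "s_rest", "s_kappa", "s_alive"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros_like(arr)]))

    def _invalidate(self):
        self._nidx = None
        self._sidx = None

    @property
    def node_ids(self) -> np.ndarray:
        if self._nidx is None:
            self._nidx = np.flatnonzero(self.n_alive_mask[: self.n_top])
        return self._nidx

    @property
    def spring_ids(self) -> np.ndarray:
        if self._sidx is None:
            self._sidx = np.flatnonzero(self.s_alive[: self.s_top])
            self._refresh_stiffsum()
        return self._sidx

    def _refresh_stiffsum(self):
        self._stiffsum[:] = 0.0
        idx = self._sidx
        np.add.at(self._stiffsum, self.si[idx], self.s_kappa[idx])
        np.add.at(self._stiffsum, self.sj[idx], self.s_kappa[idx])

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    @property
    def n_springs(self) -> int:
        return int(self.spring_ids.size)

    def positions(self, ids=None) -> np.ndarray:
        ids = self.node_ids if ids is None else np.asarray(ids)
        return np.column_stack([self.px[ids], self.py[ids]])

    # ------------------------------------------------------------------
    # construction
    def add_node(self, p, *, mobile: bool = True, birth_time: float = 0.0) -> int:
        if self.n_top == self.px.size:
            self._grow_nodes()
        i = self.n_top
        self.px[i], self.py[i] = float(p[0]), float(p[1])
        self.mobile[i] = mobile
        self.n_alive_mask[i] = True
        self.birth[i] = birth_time
        self._deg[i] = 0
        self.n_top += 1
        self._invalidate()
        return i

    def add_spring(self, i: int, j: int, rest_length: float,
                   kappa: float | None = None) -> int:
        if rest_length <= 0:
            raise ValueError("rest_length must be > 0")
        if self.s_top == self.si.size:
            self._grow_springs()
        k = self.s_top
        self.si[k], self.sj[k] = i, j
        self.s_rest[k] = rest_length
        self.s_kappa[k] = self.kappa_net if kappa is None else kappa
        self.s_alive[k] = True
        self._deg[i] += 1
        self._deg[j] += 1
        self.s_top += 1
        self._invalidate()
        return k

    def anchor_node(self, p, anchor_radius: float, max_links: int = 4,
                    *, mobile: bool = True, birth_time: float = 0.0) -> int:
        """Insert a node at ``p`` and link it by undeformed springs to the
        up-to-``max_links`` nearest live nodes within ``anchor_radius``.

        Rest lengths equal the current separations, so new springs carry no
        tension at creation.  Ties in distance break toward the lower node
        id, keeping runs deterministic.  Zero neighbours is legal: the node
        starts isolated.
        """
        if anchor_radius <= 0:
            raise ValueError("anchor_radius must be > 0")
        ids = self.node_ids
        if ids.size:
            d = np.hypot(self.px[ids] - p[0], self.py[ids] - p[1])
            near = d <= anchor_radius
            cand = ids[near]
            dc = d[near]
            order = np.lexsort((cand, dc))[:max_links]
        else:
            cand = np.empty(0, dtype=np.int64)
            order = []
        i = self.add_node(p, mobile=mobile, birth_time=birth_time)
        for k in order:
            if dc[k] > 1e-12:
                self.add_spring(i, int(cand[k]), rest_length=float(dc[k]))
        return i

    # ------------------------------------------------------------------
    # mechanics
    def spring_tension(self, ids=None) -> np.ndarray:
        """Signed tension κ·(length − rest) per live spring (>0 stretched)."""
        ids = self.spring_ids if ids is None else np.asarray(ids)
        dx = self.px[self.sj[ids]] - self.px[self.si[ids]]
        dy = self.py[self.sj[ids]] - self.py[self.si[ids]]
        return self.s_kappa[ids] * (np.hypot(dx, dy) - self.s_rest[ids])

    def net_forces(self, ext_forces=None) -> np.ndarray:
        """Net nodal force array (n_top, 2): springs plus external forces."""
        f = np.zeros((self.px.size, 2))
        idx = self.spring_ids
        i, j = self.si[idx], self.sj[idx]
        dx = self.px[j] - self.px[i]
        dy = self.py[j] - self.py[i]
        L = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            fm = np.where(L > 1e-12, self.s_kappa[idx] * (L - self.s_rest[idx]) / L, 0.0)
        np.add.at(f[:, 0], i, fm * dx)
        np.add.at(f[:, 1], i, fm * dy)
        np.add.at(f[:, 0], j, -fm * dx)
        np.add.at(f[:, 1], j, -fm * dy)
        if ext_forces is not None:
            for n, fv in ext_forces.items():
                f[n] += fv
        return f[: self.n_top]

    def elastic_energy(self) -> float:
        idx = self.spring_ids
        dx = self.px[self.sj[idx]] - self.px[self.si[idx]]
        dy = self.py[self.sj[idx]] - self.py[self.si[idx]]
        stretch = np.hypot(dx, dy) - self.s_rest[idx]
        return float(0.5 * np.sum(self.s_kappa[idx] * stretch**2))

    def relax(self, ext_forces=None, tol: float = 1e-3, max_sweeps: int = 500,
              damping: float = 0.8, strict: bool = False,
              max_shift: float = np.inf) -> RelaxResult:
        """Sweep mobile nodes toward force equilibrium.

        ``ext_forces`` may be a mapping node id → force 2-vector, or a pair
        of flat per-node arrays (fx, fy) as used by the engine hot loop.
        Nodes with no incident springs are held fixed: an isolated node has
        no elastic environment to equilibrate against and acts as a pinned
        anchor until springs connect it (this regularizes the otherwise
        ill-posed free-floating case).

        ``max_shift`` (μm) caps each node's displacement within the call;
        see :func:`mesotail._kernels.relax_sweeps`.  A node that hits the
        cap is drag-limited, not equilibrated, and does not count toward
        the residual.

        Raises :class:`RelaxationError` if ``strict`` and the residual
        tolerance (pN) is not reached within ``max_sweeps``.
        """
        sidx = self.spring_ids
        nidx = self.node_ids
        if ext_forces is None:
            fxe = np.zeros_like(self.px)
            fye = np.zeros_like(self.py)
        elif isinstance(ext_forces, tuple):
            fxe, fye = ext_forces
        else:
            fxe = np.zeros_like(self.px)
            fye = np.zeros_like(self.py)
            for n, fv in ext_forces.items():
                fxe[n] = fv[0]
                fye[n] = fv[1]
        res, sweeps = _kernels.relax_sweeps(
            self.px, self.py, self.mobile, self.si, self.sj,
            self.s_rest, self.s_kappa, sidx, fxe, fye,
            self._stiffsum, nidx, tol, max_sweeps, damping,
            self._fx, self._fy, max_shift, self._ox, self._oy,
        )
        ok = res <= tol
        if strict and not ok:
            raise RelaxationError(res, tol, sweeps)
        return RelaxResult(float(res), int(sweeps), bool(ok))

    # ------------------------------------------------------------------
    # turnover
    def remove_node(self, i: int):
        """Remove node ``i`` and every spring incident to it."""
        self.n_alive_mask[i] = False
        if self._deg[i] > 0:
            idx = self.spring_ids
            kill = idx[(self.si[idx] == i) | (self.sj[idx] == i)]
            self.s_alive[kill] = False
            self._deg[self.si[kill]] -= 1
            self._deg[self.sj[kill]] -= 1
            self._deg[i] = 0
        self._invalidate()

    def disassemble(self, k_dis: float, dt: float, rng,
                    protect=None) -> np.ndarray:
        """Remove each node independently with probability 1 − exp(−k_dis·dt)
        (bulk depolymerization at a rate proportional to node count);
        incident springs go with the node.  Nodes listed in ``protect``
        (e.g. a rigid substrate layer) are exempt.  Returns the removed ids.
        """
        if k_dis * dt > 0.1:
            raise ValueError("k_dis*dt must be <= 0.1 for the tau-leap to hold")
        if k_dis <= 0:
            return np.empty(0, dtype=np.int64)
        ids = self.node_ids
        p = -math.expm1(-k_dis * dt)
        hit = ids[rng.random(ids.size) < p]
        if protect is not None and hit.size:
            hit = hit[~np.isin(hit, protect)]
        for i in hit:
            self.n_alive_mask[i] = False
        if hit.size:
            idx = self.spring_ids
            kill = idx[~self.n_alive_mask[self.si[idx]] | ~self.n_alive_mask[self.sj[idx]]]
            self.s_alive[kill] = False
            self._deg[self.si[kill]] -= 1
            self._deg[self.sj[kill]] -= 1
            self._invalidate()
        return hit

    def rupture(self, F_rup: float) -> np.ndarray:
        """Remove springs whose tensile force exceeds ``F_rup`` (crosslink
        breakage).  Compressed springs never rupture.  Returns removed ids."""
        if F_rup <= 0:
            raise ValueError("F_rup must be > 0")
        ids = self.spring_ids
        if not ids.size:
            return ids
        kill = ids[self.spring_tension(ids) > F_rup]
        if kill.size:
            self.s_alive[kill] = False
            self._deg[self.si[kill]] -= 1
            self._deg[self.sj[kill]] -= 1
            self._invalidate()
        return kill

    def update_freeze(self, bead: Bead, d_freeze: float) -> int:
        """Freeze (irreversibly) nodes farther than ``d_freeze`` from the
        bead surface — the aged tail adhering to the substrate."""
        if d_freeze <= 0:
            raise ValueError("d_freeze must be > 0")
        return int(_kernels.freeze_pass(
            self.px, self.py, self.mobile, self.node_ids,
            bead.center[0], bead.center[1], bead.orientation,
            bead.semi_axis_a, bead.semi_axis_b, d_freeze,
        ))

    # ------------------------------------------------------------------
    # i/o
    def node_table(self):
        import pandas as pd

        ids = self.node_ids
        return pd.DataFrame({
            "id": ids, "x": self.px[ids], "y": self.py[ids],
            "mobile": self.mobile[ids], "birth_time": self.birth[ids],
        })

    def spring_table(self):
        import pandas as pd

        ids = self.spring_ids
        return pd.DataFrame({
            "i": self.si[ids], "j": self.sj[ids], "rest_length": self.s_rest[ids],
        })
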