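"""Compiled hot loops.

Everything here is numba-jitted and operates on flat arrays owned by the
Python-level containers (:class:`~mesotail.gel.GelNetwork`,
:class:`~mesotail.filaments.FilamentSystem`).  The public modules wrap these
kernels; nothing outside the package should import this module directly.

Conventions: node/spring/filament arrays are over-allocated with ``alive``
masks; kernels receive explicit index arrays of live entries so iteration
order (by id) is deterministic.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi

# filament states
FREE = 0
ATTACHED = 1


@njit(cache=True)
def nearest_param(a, b, x, y):
    """Parameter t of the surface point of the ellipse (a cos t, b sin t)
    nearest to the body-frame point (x, y).

    Newton iteration on the stationarity condition of the squared distance,
    started from the scaled-angle heuristic; falls back to a dense scan plus
    local refinement when Newton stalls (deep-interior or near-focus points).
    """
    t = math.atan2(a * y, b * x)
    ok = False
    for _ in range(40):
        c = math.cos(t)
        s = math.sin(t)
        h = a * x * s - b * y * c - (a * a - b * b) * s * c
        hp = a * x * c + b * y * s - (a * a - b * b) * (c * c - s * s)
        if hp <= 1e-14:
            break
        step = h / hp
        if step > 0.3:
            step = 0.3
        elif step < -0.3:
            step = -0.3
        t -= step
        if abs(step) < 1e-13:
            ok = True
            break
    if not ok:
        # dense scan + Newton polish from the best sample
        best_t = 0.0
        best_d = 1e300
        for k in range(256):
            tt = TWO_PI * k / 256.0
            dx = x - a * math.cos(tt)
            dy = y - b * math.sin(tt)
            d = dx * dx + dy * dy
            if d < best_d:
                best_d = d
                best_t = tt
        t = best_t
        for _ in range(40):
            c = math.cos(t)
            s = math.sin(t)
            h = a * x * s - b * y * c - (a * a - b * b) * s * c
            hp = a * x * c + b * y * s - (a * a - b * b) * (c * c - s * s)
            if abs(hp) <= 1e-14:
                break
            step = h / hp
            if step > 0.05:
                step = 0.05
            elif step < -0.05:
                step = -0.05
            t -= step
            if abs(step) < 1e-13:
                break
    t = t % TWO_PI
    return t


@njit(cache=True)
def surface_geometry(a, b, t):
    """Body-frame surface point and outward unit normal at parameter t."""
    c = math.cos(t)
    s = math.sin(t)
    qx = a * c
    qy = b * s
    # gradient of the implicit form (x/a)^2 + (y/b)^2
    nx = c / a
    ny = s / b
    nn = math.sqrt(nx * nx + ny * ny)
    return qx, qy, nx / nn, ny / nn


@njit(cache=True)
def signed_gap(a, b, x, y):
    """Signed distance from body-frame point (x, y) to the ellipse surface:
    positive outside, negative inside (i.e. minus the penetration depth)."""
    t = nearest_param(a, b, x, y)
    qx, qy, nx, ny = surface_geometry(a, b, t)
    return (x - qx) * nx + (y - qy) * ny


@njit(cache=True)
def relax_sweeps(px, py, movable, si, sj, rest, kap, sidx,
                 fxext, fyext, stiffsum, nidx,
                 tol, max_sweeps, damping, fx, fy, max_shift,
                 ox, oy):
    """Damped Jacobi relaxation of the spring network.

    Each sweep recomputes net nodal forces (springs + external) and moves
    every movable node along its force scaled by damping / (sum of incident
    spring stiffnesses).  Nodes without springs have no elastic environment
    and are held in place (they act as pinned anchors until linked).

    ``max_shift`` caps each node's total displacement within this call: a
    floating connected cluster under a net external force has no
    equilibrium, and the cap acts as the viscous drag that lets such
    clusters drift at a bounded rate instead of diverging.  Pass inf for a
    pure equilibration.  ``ox``/``oy`` are scratch for the origin positions.

    Returns (residual, sweeps_used); residual is the max |net force| over
    movable connected nodes at the *returned* positions (capped nodes are
    excluded from the residual — they are drag-limited, not equilibrated).
    """
    res = 0.0
    sweeps = 0
    capped = max_shift != np.inf
    if capped:
        for k in nidx:
            ox[k] = px[k]
            oy[k] = py[k]
    for sweep in range(max_sweeps + 1):
        for k in nidx:
            fx[k] = fxext[k]
            fy[k] = fyext[k]
        for m in sidx:
            i = si[m]
            j = sj[m]
            dx = px[j] - px[i]
            dy = py[j] - py[i]
            L = math.sqrt(dx * dx + dy * dy)
            if L > 1e-12:
                fm = kap[m] * (L - rest[m]) / L
                fx[i] += fm * dx
                fy[i] += fm * dy
                fx[j] -= fm * dx
                fy[j] -= fm * dy
        res = 0.0
        for k in nidx:
            if movable[k] and stiffsum[k] > 0.0:
                if capped:
                    dx = px[k] - ox[k]
                    dy = py[k] - oy[k]
                    if dx * dx + dy * dy >= max_shift * max_shift:
                        continue
                r = math.sqrt(fx[k] * fx[k] + fy[k] * fy[k])
                if r > res:
                    res = r
        if res <= tol or sweep == max_sweeps:
            sweeps = sweep
            break
        for k in nidx:
            if movable[k] and stiffsum[k] > 0.0:
                px[k] += damping * fx[k] / stiffsum[k]
                py[k] += damping * fy[k] / stiffsum[k]
                if capped:
                    dx = px[k] - ox[k]
                    dy = py[k] - oy[k]
                    d = math.sqrt(dx * dx + dy * dy)
                    if d > max_shift:
                        px[k] = ox[k] + dx / d * max_shift
                        py[k] = oy[k] + dy / d * max_shift
    return res, sweeps


@njit(cache=True)
def filament_pass(fidx, state, anchor, t_att, rest, t_contact,
                  px, py,
                  cx, cy, th, a, b,
                  kf, push_cap,
                  kdet0, Fd, katt, kcap, Vmax, fexp, dt,
                  u, removed, fxext, fyext, do_kinetics):
    """One kinetic + mechanical update of all live filaments.

    Per filament: evaluate the current load, draw the tau-leaped state
    transition (Bell-law detachment, constant-rate re-attachment and capping),
    grow free filaments by the ratchet law, then accumulate the post-update
    forces: pushes on the bead along the inward surface normal at the contact
    point (reaction outward on the anchor node), pulls at the attachment site
    for stretched attached filaments.  Newton's third law holds exactly.

    Mutates state/t_att/rest/t_contact/removed and the external-force
    accumulators; returns the bead wrench and diagnostic counts.
    """
    cth = math.cos(th)
    sth = math.sin(th)
    Fx = 0.0
    Fy = 0.0
    Tq = 0.0
    n_push = 0
    n_att = 0
    sc = 0.0
    ss = 0.0
    p_att = 1.0 - math.exp(-katt * dt)
    p_cap = 1.0 - math.exp(-kcap * dt)
    for kk in range(fidx.shape[0]):
        i = fidx[kk]
        ai = anchor[i]
        # anchor position in body frame
        wx = px[ai] - cx
        wy = py[ai] - cy
        bx = cth * wx + sth * wy
        by = -sth * wx + cth * wy
        tq = nearest_param(a, b, bx, by)
        qx, qy, nx, ny = surface_geometry(a, b, tq)
        gap = (bx - qx) * nx + (by - qy) * ny  # >0: anchor outside
        t_contact[i] = tq

        if state[i] == ATTACHED:
            # current tension from the attachment-site spring
            sx, sy, _, _ = surface_geometry(a, b, t_att[i])
            dxb = bx - sx
            dyb = by - sy
            d = math.sqrt(dxb * dxb + dyb * dyb)
            ext = d - rest[i]
            Ft = kf * ext if ext > 0.0 else 0.0
            p_det = 1.0 - math.exp(-kdet0 * math.exp(Ft / Fd) * dt)
            if do_kinetics and u[kk, 0] < p_det:
                state[i] = FREE
            else:
                if ext > 0.0 and d > 1e-12:
                    # pull on the bead at the attachment site, toward the anchor
                    fmag = kf * ext
                    ux = dxb / d
                    uy = dyb / d
                    # world frame
                    fx_w = fmag * (cth * ux - sth * uy)
                    fy_w = fmag * (sth * ux + cth * uy)
                    rx = cth * sx - sth * sy
                    ry = sth * sx + cth * sy
                    Fx += fx_w
                    Fy += fy_w
                    Tq += rx * fy_w - ry * fx_w
                    fxext[ai] -= fx_w
                    fyext[ai] -= fy_w
                n_att += 1
                continue
        else:
            if do_kinetics and u[kk, 0] < p_att:
                # re-attach, undeformed, at the current nearest surface point
                state[i] = ATTACHED
                t_att[i] = tq
                rest[i] = gap if gap > 0.0 else 0.0
                n_att += 1
                continue
            elif do_kinetics and u[kk, 1] < p_cap:
                removed[kk] = 1
                continue
            elif do_kinetics:
                pen = rest[i] - gap
                Fp = kf * pen if pen > 0.0 else 0.0
                if Fp > push_cap:
                    Fp = push_cap
                rest[i] += Vmax * math.exp(-Fp * fexp) * dt

        # free (or freshly detached) filament: push if the grown tip overlaps
        pen = rest[i] - gap
        if pen > 0.0:
            Fp = kf * pen
            if Fp > push_cap:
                Fp = push_cap
            # push on the bead along the inward normal (away from the anchor)
            fx_w = -Fp * (cth * nx - sth * ny)
            fy_w = -Fp * (sth * nx + cth * ny)
            rx = cth * qx - sth * qy
            ry = sth * qx + cth * qy
            Fx += fx_w
            Fy += fy_w
            Tq += rx * fy_w - ry * fx_w
            fxext[ai] -= fx_w
            fyext[ai] -= fy_w
            n_push += 1
            # world angle of the contact point about the bead center
            phi = math.atan2(ry, rx)
            sc += math.cos(phi)
            ss += math.sin(phi)
    return Fx, Fy, Tq, n_push, n_att, sc, ss


@njit(cache=True)
def maintenance_pass(px, py, si, sj, rest, kap, sidx, s_alive,
                     n_alive, deg, nidx, u, p_remove, F_rup,
                     mobile, cx, cy, th, a, b, d_freeze, do_freeze):
    """Fused per-step network turnover: crosslink rupture (tension > F_rup),
    stochastic node removal with per-node probability ``p_remove`` (springs
    cascade), and far-field freezing.  Returns (ruptures, removals, frozen).
    The engine uses this path; the individual gel operations implement the
    same rules one at a time."""
    n_rupt = 0
    for m in sidx:
        i = si[m]
        j = sj[m]
        dx = px[j] - px[i]
        dy = py[j] - py[i]
        L = math.sqrt(dx * dx + dy * dy)
        if kap[m] * (L - rest[m]) > F_rup:
            s_alive[m] = False
            deg[i] -= 1
            deg[j] -= 1
            n_rupt += 1
    n_rem = 0
    for kk in range(nidx.shape[0]):
        k = nidx[kk]
        if u[kk] < p_remove:
            n_alive[k] = False
            n_rem += 1
    if n_rem > 0:
        for m in sidx:
            if s_alive[m] and (not n_alive[si[m]] or not n_alive[sj[m]]):
                s_alive[m] = False
                deg[si[m]] -= 1
                deg[sj[m]] -= 1
    n_frozen = 0
    if do_freeze:
        n_frozen = freeze_pass(px, py, mobile, nidx, cx, cy, th, a, b, d_freeze)
    return n_rupt, n_rem, n_frozen


@njit(cache=True)
def freeze_pass(px, py, mobile, nidx, cx, cy, th, a, b, d_freeze):
    """Irreversibly immobilize nodes farther than d_freeze from the bead
    surface.  Cheap radial bounds skip the Newton solve for most nodes."""
    cth = math.cos(th)
    sth = math.sin(th)
    n_frozen = 0
    for k in nidx:
        if not mobile[k]:
            continue
        wx = px[k] - cx
        wy = py[k] - cy
        rr = math.sqrt(wx * wx + wy * wy)
        if rr - b <= d_freeze:
            # surface distance <= rr - b (and interior points are closer
            # still): certainly within reach, stays mobile
            continue
        if rr - a > d_freeze:
            mobile[k] = False
            n_frozen += 1
            continue
        bx = cth * wx + sth * wy
        by = -sth * wx + cth * wy
        g = signed_gap(a, b, bx, by)
        if g > d_freeze:
            mobile[k] = False
            n_frozen += 1
    return n_frozen
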