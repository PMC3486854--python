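"""Rigid-body motion of the obstacle.

The bead carries no inertia: it moves and rotates overdamped under the net
force and torque of all interacting filaments, with mobilities large enough
that it sits near force/torque balance between kinetic events (the
quasi-static propulsion limit).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filaments import FilamentSystem, filament_force
from .gel import GelNetwork
from .geometry import Bead

__all__ = ["Wrench", "net_wrench", "advance_bead", "StepSizeError"]


class StepSizeError(RuntimeError):
    """Per-step displacement exceeded a tenth of the short semi-axis."""


@dataclass
class Wrench:
    """Planar force (pN) and torque about the bead center (pN·μm, z)."""

    force: np.ndarray = field(default_factory=lambda: np.zeros(2))
    torque: float = 0.0


def net_wrench(fils: FilamentSystem, bead: Bead, net: GelNetwork) -> Wrench:
    """Sum of all filament forces and their torques about the bead center.

    Pushes act at the nearest surface point of the filament, pulls at the
    attachment site.  This is the readable reference path; the engine's hot
    loop accumulates the same sums inside the filament kernel (the two are
    cross-checked in the test suite).
    """
    F = np.zeros(2)
    T = 0.0
    for i in fils.ids:
        f, _, r = filament_force(fils, i, bead, net)
        F += f
        T += float(np.cross(r - bead.center, f))
    return Wrench(F, T)


def advance_bead(bead: Bead, w: Wrench, dt: float) -> Bead:
    """Overdamped pose update: center += μ_t·F·dt, orientation += μ_r·T·dt.

    Raises :class:`StepSizeError` if the translation exceeds 0.1·b, the
    guard for the explicit scheme.
    """
    dx = bead.mobility_t * np.asarray(w.force, float) * dt
    if np.hypot(*dx) > 0.1 * bead.semi_axis_b:
        raise StepSizeError(
            f"bead displacement {np.hypot(*dx):.3g} um in one step exceeds "
            f"0.1*b = {0.1 * bead.semi_axis_b:.3g} um; reduce dt"
        )
    bead.center = bead.center + dx
    bead.orientation = float(bead.orientation + bead.mobility_r * w.torque * dt)
    return bead
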