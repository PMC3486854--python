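"""Rigid elliptical obstacle: surface parametrization, normals, penetration.

The propelled obstacle (a polystyrene bead, in the motility assays this model
emulates) is a rigid 2D ellipse with semi-axes ``a >= b``, a center and an
orientation angle of its long axis.  Filaments interact with the bead through
its surface: pushes act along the surface normal at the contact point, so all
contact queries reduce to nearest-point problems on the ellipse, which have no
closed form and are solved by safeguarded Newton iteration (see
:mod:`mesotail._kernels`).

Lengths are in micrometres, angles in radians.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe

from . import _kernels

__all__ = [
    "Bead",
    "surface_point",
    "outward_normal",
    "penetration_depth",
    "nearest_surface",
]


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class Bead:
    """Rigid 2D ellipse with overdamped translational/rotational mobilities.

    Parameters
    ----------
    semi_axis_a, semi_axis_b:
        Semi-axes in μm, ``a`` along the body long axis; ``a >= b > 0``.
    center, orientation:
        Pose: lab-frame center (μm) and angle of the long axis vs the lab
        x-axis (rad).
    mobility_t, mobility_r:
        Overdamped mobilities, μm·s⁻¹·pN⁻¹ and rad·s⁻¹·(pN·μm)⁻¹.
    """

    semi_axis_a: float
    semi_axis_b: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    orientation: float = 0.0
    mobility_t: float = 0.05
    mobility_r: float = 0.1

    def __post_init__(self):
        if not (self.semi_axis_a >= self.semi_axis_b > 0):
            raise ValueError("require semi_axis_a >= semi_axis_b > 0")
        self.center = np.asarray(self.center, dtype=float)
        self._arc_t = None
        self._arc_s = None
        self._perimeter = None

    # -- constructors -------------------------------------------------
    @classmethod
    def from_area_aspect(cls, area: float, aspect: float, **kw) -> "Bead":
        """Ellipse of given area πab and aspect ratio a/b.

        Aspect-ratio sweeps in the orientation experiments hold the bead
        area constant, so this is the canonical constructor there.
        """
        b = math.sqrt(area / (math.pi * aspect))
        return cls(semi_axis_a=aspect * b, semi_axis_b=b, **kw)

    # -- derived geometry ---------------------------------------------
    @property
    def aspect_ratio(self) -> float:
        return self.semi_axis_a / self.semi_axis_b

    @property
    def area(self) -> float:
        return math.pi * self.semi_axis_a * self.semi_axis_b

    @property
    def perimeter(self) -> float:
        if self._perimeter is None:
            a, b = self.semi_axis_a, self.semi_axis_b
            self._perimeter = float(4 * a * ellipe(1 - (b / a) ** 2))
        return self._perimeter

    # -- frames ---------------------------------------------------------
    def to_body(self, p) -> np.ndarray:
        return _rot(-self.orientation) @ (np.asarray(p, float) - self.center)

    def to_world(self, q) -> np.ndarray:
        return self.center + _rot(self.orientation) @ np.asarray(q, float)

    def long_axis(self) -> np.ndarray:
        """Unit vector of the body long axis in the lab frame."""
        return np.array([math.cos(self.orientation), math.sin(self.orientation)])

    # -- arclength table (cached; geometry is fixed during a run) -------
    def _arc_table(self):
        if self._arc_t is None:
            t = np.linspace(0.0, 2 * math.pi, 2049)
            ds = np.hypot(-self.semi_axis_a * np.sin(t), self.semi_axis_b * np.cos(t))
            s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(t))])
            self._arc_t, self._arc_s = t, s
        return self._arc_t, self._arc_s

    def arclength_of_param(self, t: float) -> float:
        tt, ss = self._arc_table()
        return float(np.interp(t % (2 * math.pi), tt, ss))

    def param_at_arclength(self, s) -> np.ndarray:
        """Inverse of :meth:`arclength_of_param` (vectorized, wraps)."""
        tt, ss = self._arc_table()
        s = np.asarray(s, float) % ss[-1]
        return np.interp(s, ss, tt)

    def speed_of_param(self, t: float) -> float:
        """|ds/dt| at parameter t."""
        return math.hypot(-self.semi_axis_a * math.sin(t), self.semi_axis_b * math.cos(t))


def surface_point(bead: Bead, t: float) -> np.ndarray:
    """Lab-frame surface point at parameter ``t``:
    center + Rot(orientation)·(a cos t, b sin t)."""
    q = np.array([bead.semi_axis_a * math.cos(t), bead.semi_axis_b * math.sin(t)])
    return bead.to_world(q)


def outward_normal(bead: Bead, t: float) -> np.ndarray:
    """Unit outward normal at the surface point of parameter ``t``.

    Filaments push perpendicularly to the obstacle surface, so this normal
    fixes every contact-force direction in the model.
    """
    _, _, nx, ny = _kernels.surface_geometry(bead.semi_axis_a, bead.semi_axis_b, t)
    return _rot(bead.orientation) @ np.array([nx, ny])


def nearest_surface(bead: Bead, p) -> tuple[np.ndarray, float, float]:
    """Nearest surface point to lab-frame point ``p``.

    Returns ``(q, t, gap)`` with ``q`` the lab-frame nearest surface point,
    ``t`` its parameter, and ``gap`` the signed distance along the outward
    normal (positive outside the bead, negative inside).
    """
    bp = bead.to_body(p)
    t = _kernels.nearest_param(bead.semi_axis_a, bead.semi_axis_b, bp[0], bp[1])
    qx, qy, nx, ny = _kernels.surface_geometry(bead.semi_axis_a, bead.semi_axis_b, t)
    gap = (bp[0] - qx) * nx + (bp[1] - qy) * ny
    return bead.to_world([qx, qy]), float(t), float(gap)


def penetration_depth(bead: Bead, p) -> float:
    """Signed depth of point ``p`` inside the bead.

    Positive inside (equal to the distance to the nearest surface point),
    zero on the surface, negative outside (minus the clearance).  Free
    filaments convert the virtual penetration of their barbed end into a
    Hookean pushing force.
    """
    _, _, gap = nearest_surface(bead, p)
    return -gap
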