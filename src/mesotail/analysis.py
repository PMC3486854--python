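"""Track processing and statistics.

Mirrors how bead-motility tracks are analyzed: positions are smoothed by a
local cubic (Savitzky–Golay) filter, the trajectory curvature is the
angular velocity of the heading divided by the instantaneous speed,
κ = ω/v, and the distribution of κ across a run is summarized by its root
mean square, its shape relative to a matched Gaussian, and its
autocorrelation length along the path.  The same module classifies the
propulsion orientation of elongated beads, the concavity class of
force-velocity curves, and fits the filament-number fluctuation model of
trajectory curvature.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.signal import savgol_filter

__all__ = [
    "smooth_path", "curvature_series", "CurvatureSeries", "kappa_stats",
    "KappaStats", "classify_orientation", "OrientationClassification",
    "concavity_classify", "entrapment_events", "scaling_fit",
    "ScalingRow", "ScalingFit",
]


def smooth_path(track: np.ndarray, window: int = 5) -> np.ndarray:
    """Local cubic smoothing of a position series, per coordinate.

    A Savitzky–Golay filter of odd ``window`` (default five nearest
    neighbours) and cubic order: exact on cubic inputs, with one-sided
    polynomial fits at the ends so endpoints are preserved.  Tracks shorter
    than the window pass through unchanged with a warning.
    """
    track = np.asarray(track, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if track.shape[0] < window:
        warnings.warn("track shorter than smoothing window; passthrough")
        return track.copy()
    return savgol_filter(track, window, polyorder=3, axis=0, mode="interp")


@dataclass
class CurvatureSeries:
    """Per-sample speed v (μm/s), angular velocity ω (rad/s) and curvature
    κ = ω/v (μm⁻¹); κ is NaN-masked where v < v_min."""

    t: np.ndarray
    v: np.ndarray
    omega: np.ndarray
    kappa: np.ndarray
    v_min: float

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.kappa)


def curvature_series(track: np.ndarray, dt: float,
                     v_min_frac: float = 0.01) -> CurvatureSeries:
    """Curvature of a (smoothed) track: ω from the central-differenced
    unwrapped heading of the velocity, divided by the speed.

    Samples with v below ``v_min_frac`` of the median speed are masked —
    the heading (and hence κ) is undefined for a stalled bead.
    """
    track = np.asarray(track, dtype=float)
    vx = np.gradient(track[:, 0], dt)
    vy = np.gradient(track[:, 1], dt)
    v = np.hypot(vx, vy)
    heading = np.unwrap(np.arctan2(vy, vx))
    omega = np.gradient(heading, dt)
    v_min = v_min_frac * float(np.median(v))
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(v >= v_min, omega / v, np.nan)
    if not np.isfinite(kappa).any():
        raise ValueError("all curvature samples are masked (bead never moves)")
    n = track.shape[0]
    t = np.arange(n) * dt
    return CurvatureSeries(t=t, v=v, omega=omega, kappa=kappa, v_min=v_min)


@dataclass
class KappaStats:
    kappa_rms: float          # μm⁻¹
    excess_kurtosis: float    # 0 for a Gaussian
    ks_distance: float        # KS distance to a matched zero-mean Gaussian
    autocorr_length: float    # arclength (μm) where autocorrelation < 1/e


def kappa_stats(cs: CurvatureSeries, min_samples: int = 100) -> KappaStats:
    """Summary statistics of a curvature series (see :class:`KappaStats`)."""
    k = cs.kappa[cs.valid]
    if k.size < min_samples:
        raise ValueError(f"need >= {min_samples} unmasked curvature samples, got {k.size}")
    rms = float(np.sqrt(np.mean(k**2)))
    kurt = float(stats.kurtosis(k, fisher=True, bias=False))
    ks = float(stats.kstest(k, stats.norm(loc=0.0, scale=np.std(k)).cdf).statistic)

    # autocorrelation vs mean arclength lag
    kc = k - k.mean()
    var = float(np.mean(kc**2))
    ds = float(np.mean(cs.v[cs.valid])) * float(np.mean(np.diff(cs.t)))
    acl = ds * k.size
    if var > 0:
        for lag in range(1, k.size // 2):
            c = float(np.mean(kc[:-lag] * kc[lag:])) / var
            if c < 1.0 / math.e:
                acl = ds * lag
                break
    return KappaStats(rms, kurt, ks, acl)


# ----------------------------------------------------------------------
# orientation of elongated beads

@dataclass
class OrientationClassification:
    fractions: dict          # time fraction in each class, over valid samples
    label: str               # modal class over the final two-thirds of the run
    phi_deg: np.ndarray      # per-sample velocity/long-axis angle, folded to [0, 90]


def classify_orientation(traj, bins_deg: tuple[float, float] = (30.0, 60.0),
                         v_min_frac: float = 0.01,
                         smooth_window: int = 5) -> OrientationClassification:
    """Classify the propulsion orientation of an elongated bead.

    Per sample, φ is the angle between the velocity direction and the body
    long axis folded to [0°, 90°]; the sample is *long* for φ below the
    first bin edge, *short* above the second, otherwise *skewed* (the equal
    tri-partition of [0°, 90°] is the default, exposed via ``bins_deg``).
    Samples slower than ``v_min_frac``·median speed are dropped.  The run
    label is the modal class over the final two-thirds of the run, skipping
    the initial symmetry-breaking transient.
    """
    t = np.asarray(traj.t, float)
    xy = smooth_path(np.column_stack([traj.x, traj.y]), smooth_window)
    theta = np.asarray(traj.theta, float)
    dt = float(np.median(np.diff(t)))
    vx = np.gradient(xy[:, 0], dt)
    vy = np.gradient(xy[:, 1], dt)
    v = np.hypot(vx, vy)
    ok = v >= v_min_frac * np.median(v)
    phi = np.arctan2(vy, vx) - theta
    phi = np.abs((phi + np.pi / 2) % np.pi - np.pi / 2)  # fold to [0, pi/2]
    phi = np.degrees(phi)
    lo, hi = bins_deg
    cls = np.where(phi < lo, 0, np.where(phi > hi, 2, 1))
    names = np.array(["long", "skewed", "short"])
    fr = {nm: float(np.mean(cls[ok] == i)) if ok.any() else np.nan
          for i, nm in enumerate(names)}
    tail = ok & (np.arange(t.size) >= t.size // 3)
    if not tail.any():
        tail = ok
    counts = np.bincount(cls[tail], minlength=3)
    return OrientationClassification(fractions=fr, label=str(names[np.argmax(counts)]),
                                     phi_deg=phi)


# ----------------------------------------------------------------------
# force-velocity concavity

def _normalize_fv(F, V):
    F = np.asarray(F, float)
    V = np.asarray(V, float)
    order = np.argsort(F)
    F, V = F[order], V[order]
    # keep at most one stalled point: a long zero tail past stall carries no
    # shape information and would swamp the template residuals
    nz = np.flatnonzero(V > 0)
    if nz.size == 0:
        raise ValueError("curve has no positive velocities")
    last = min(nz[-1] + 1, V.size - 1)
    F, V = F[:last + 1], V[:last + 1]
    Vm = V.max()
    if Vm <= 0:
        raise ValueError("velocities are non-positive")
    Vn = V / Vm
    # force at half-maximal velocity, by interpolation on the decreasing curve
    below = np.flatnonzero(Vn <= 0.5)
    if below.size == 0:
        raise ValueError("curve never falls to half-maximal velocity")
    j = below[0]
    if j == 0:
        F_half = F[0]
    else:
        F_half = float(np.interp(0.5, [Vn[j], Vn[j - 1]], [F[j], F[j - 1]]))
    if F_half <= 0:
        raise ValueError("degenerate half-velocity force")
    return F / F_half, Vn


def concavity_classify(F, V, indeterminate_band: float = 0.10) -> str:
    """Classify a force-velocity curve as ``concave_up`` / ``concave_down``.

    The curve is normalized by its maximal velocity and by the force at
    half-maximal velocity, then fit by two templates pinned to V(1) = 1/2:
    an exponential decay 2^(−F) (the ratchet-like concave-up shape) and a
    plateau-then-linear-crash (the load-insensitive concave-down shape,
    with the plateau length as the free parameter).  The label follows the
    lower residual; curves whose template residuals differ by less than
    ``indeterminate_band`` (relative) are ``indeterminate``.
    """
    Fn, Vn = _normalize_fv(F, V)
    if Fn.size < 6:
        raise ValueError("need >= 6 points after normalization")
    r_up = float(np.sqrt(np.mean((Vn - 2.0 ** (-Fn)) ** 2)))

    def down(Fc):
        out = np.clip(1.0 - (Fn - Fc) / (2.0 - 2.0 * Fc), 0.0, 1.0)
        return float(np.sqrt(np.mean((Vn - out) ** 2)))

    # the plateau must be a genuine plateau: its lower bound is set so a
    # straight line sits equidistant from both templates (ambiguous shape)
    res = optimize.minimize_scalar(down, bounds=(0.37, 0.95), method="bounded")
    r_down = float(res.fun)
    hi, lo = max(r_up, r_down), min(r_up, r_down)
    if hi - lo <= indeterminate_band * hi:
        return "indeterminate"
    return "concave_up" if r_up < r_down else "concave_down"


# ----------------------------------------------------------------------
# entrapment

def entrapment_events(traj, speed_frac: float = 0.1, min_duration: float = 60.0,
                      smooth_window: int = 5) -> int:
    """Count entrapment events: contiguous stretches where the smoothed
    speed stays below ``speed_frac`` of the run-median speed for at least
    ``min_duration`` seconds — the bead transiently arrested inside its own
    actin cloud."""
    t = np.asarray(traj.t, float)
    xy = smooth_path(np.column_stack([traj.x, traj.y]), smooth_window)
    dt = float(np.median(np.diff(t)))
    v = np.hypot(np.gradient(xy[:, 0], dt), np.gradient(xy[:, 1], dt))
    slow = v < speed_frac * np.median(v)
    n_events = 0
    run = 0
    for s in slow:
        if s:
            run += 1
        else:
            if run * dt >= min_duration:
                n_events += 1
            run = 0
    if run * dt >= min_duration:
        n_events += 1
    return n_events


# ----------------------------------------------------------------------
# fluctuation-model scaling of trajectory curvature

@dataclass
class ScalingRow:
    """One run's inputs to the curvature fluctuation model.

    A bead propelled by N randomly placed rear filaments feels a √N
    left/right number imbalance; each biased filament deflects the heading
    by the angular spread Δθ of the contact points, and the bias persists
    for the network turnover time τ.  The predicted curvature is then
    κ_rms ≈ Δθ/(√N·v·τ), i.e. 1/κ_rms grows linearly with v·τ·√N/Δθ.
    """

    kappa_rms: float   # measured, μm⁻¹
    N: float           # mean pushing filament count
    tau: float         # network turnover time, s
    dtheta: float      # angular spread of pushing contacts, rad
    v: float           # mean speed, μm/s
    R: float = np.nan  # bead radius, μm (bookkeeping)

    @property
    def predictor(self) -> float:
        return self.v * self.tau * math.sqrt(self.N) / self.dtheta


@dataclass
class ScalingFit:
    slope: float
    correlation: float
    predictor: np.ndarray
    inv_kappa_rms: np.ndarray


def scaling_fit(rows) -> ScalingFit:
    """Regress 1/κ_rms on the fluctuation-model predictor v·τ·√N/Δθ.

    Returns the through-origin slope and the Pearson correlation across
    runs.  Requires at least six runs and non-degenerate angular spreads.
    """
    rows = list(rows)
    if len(rows) < 6:
        raise ValueError("need >= 6 runs")
    if any(not np.isfinite(r.dtheta) or r.dtheta <= 0 for r in rows):
        raise ValueError("degenerate angular spread in at least one run")
    x = np.array([r.predictor for r in rows])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite predictor in at least one run")
    y = np.array([1.0 / r.kappa_rms for r in rows])
    slope = float(np.sum(x * y) / np.sum(x * x))
    r = float(stats.pearsonr(x, y).statistic)
    return ScalingFit(slope=slope, correlation=r, predictor=x, inv_kappa_rms=y)
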