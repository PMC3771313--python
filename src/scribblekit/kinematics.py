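"""Differential-geometric analysis of planar hand trajectories.

Continuous 2-D drawing movements obey the two-thirds power law
``A = K * C**(2/3)`` relating angular speed *A* to path curvature *C*.
The law is equivalent to moving at constant *equi-affine* speed, i.e.
constant speed with respect to the arc length of equi-affine geometry —
the geometry invariant under area-preserving linear maps (det = 1).  In
that geometry parabolas play the role that straight lines play in
Euclidean geometry: they are exactly the curves of zero equi-affine
curvature.  This module provides the kinematic quantities needed by all
downstream stages: velocities and accelerations, Euclidean speed and
(unsigned) curvature, angular speed, equi-affine speed and signed
equi-affine curvature, power-law fits, and det-1 affine transforms.

Units are mm, s and radians throughout; equi-affine speed carries units
of mm^(2/3)/s and equi-affine curvature mm^(-4/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

__all__ = [
    "Trajectory",
    "KinematicProfile",
    "PowerLawFit",
    "differentiate",
    "euclidean_curvature",
    "equi_affine_speed",
    "equi_affine_curvature",
    "power_law_fit",
    "equi_affine_transform",
]

# Floors below which log-domain quantities are treated as undefined.
V_FLOOR = 1.0       # mm/s
C_FLOOR = 1e-4      # 1/mm


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled planar path (t in s, x and y in mm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("t, x, y must be equal-length 1-D arrays of length >= 2")
        if not (np.isfinite(t).all() and np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("trajectory contains non-finite values")
        dt = np.diff(t)
        if dt.min() <= 0:
            raise ValueError("t must be strictly increasing")
        step = dt.mean()
        if np.abs(dt - step).max() > 1e-9 * max(abs(t[-1]), 1.0):
            raise ValueError("sampling must be uniform (1e-9 relative tolerance)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def dt(self) -> float:
        return float((self.t[-1] - self.t[0]) / (len(self.t) - 1))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class KinematicProfile:
    """Per-sample kinematics aligned to a :class:`Trajectory`.

    ``defined`` flags interior samples where the centered stencils were
    usable; end samples use one-sided stencils and are flagged False.
    """

    traj: Trajectory
    vx: np.ndarray
    vy: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    defined: np.ndarray

    speed: np.ndarray = field(init=False)
    curvature: np.ndarray = field(init=False)
    angular_speed: np.ndarray = field(init=False)
    ea_speed: np.ndarray = field(init=False)
    curvature_defined: np.ndarray = field(init=False)

    def __post_init__(self):
        self.speed = np.hypot(self.vx, self.vy)
        cross = self.vx * self.ay - self.vy * self.ax
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(cross) / self.speed**3
        self.curvature_defined = self.defined & (self.speed > V_FLOOR)
        c[~self.curvature_defined] = np.nan
        self.curvature = c
        self.angular_speed = self.curvature * self.speed
        self.ea_speed = np.cbrt(np.abs(cross))


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of log A = log K + beta * log C."""

    beta: float
    K: float
    r2: float
    n_samples: int


def differentiate(traj: Trajectory, smooth_window: int = 11, polyorder: int = 3) -> KinematicProfile:
    """Estimate velocity and acceleration of a sampled path.

    The path is smoothed by a Savitzky-Golay local polynomial filter and
    the filter's analytic derivatives are used, which is equivalent to
    smoothed central differences on the interior.  ``smooth_window`` must
    be odd, >= 3 (>= 5 for acceleration) and shorter than the record.
    """
    if smooth_window % 2 == 0 or smooth_window < 3:
        raise ValueError("smooth_window must be odd and >= 3")
    if smooth_window >= len(traj):
        raise ValueError(
            f"trajectory of length {len(traj)} is shorter than smooth_window {smooth_window}"
        )
    polyorder = min(polyorder, smooth_window - 1)
    dt = traj.dt
    vx = savgol_filter(traj.x, smooth_window, polyorder, deriv=1, delta=dt)
    vy = savgol_filter(traj.y, smooth_window, polyorder, deriv=1, delta=dt)
    if polyorder >= 2:
        ax = savgol_filter(traj.x, smooth_window, polyorder, deriv=2, delta=dt)
        ay = savgol_filter(traj.y, smooth_window, polyorder, deriv=2, delta=dt)
    else:
        ax = np.zeros_like(vx)
        ay = np.zeros_like(vy)
    half = smooth_window // 2
    defined = np.zeros(len(traj), dtype=bool)
    defined[half:len(traj) - half] = True
    return KinematicProfile(traj, vx, vy, ax, ay, defined)


def euclidean_curvature(profile: KinematicProfile) -> np.ndarray:
    """Unsigned curvature ``|x' y'' - y' x''| / v**3`` (NaN where v is below floor)."""
    if not profile.curvature_defined.any():
        warnings.warn("speed never exceeds the floor; curvature undefined everywhere")
    return profile.curvature


def equi_affine_speed(profile: KinematicProfile) -> np.ndarray:
    """Equi-affine speed ``|x' y'' - y' x''|**(1/3)``.

    Zero exactly where velocity and acceleration are collinear (straight
    motion); constant along any parabola traversed at constant
    acceleration, in which case it equals the power-law gain K.
    """
    return profile.ea_speed


def _signed_area(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def equi_affine_transform(traj: Trajectory, a: float, b: float, c: float,
                          d: float, e: float, f: float) -> Trajectory:
    """Apply u = ax+by+c, w = dx+ey+f with the area-preserving condition ae-bd = 1."""
    if abs(a * e - b * d - 1.0) > 1e-9:
        raise ValueError("equi-affine transform requires ae - bd = 1")
    return Trajectory(traj.t, a * traj.x + b * traj.y + c, d * traj.x + e * traj.y + f)


def equi_affine_curvature(traj: Trajectory, smooth_window: int = 11,
                          n_sigma: int | None = None,
                          sigma_floor: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Signed equi-affine curvature kappa along a trajectory.

    The curve is reparametrized by equi-affine arc length sigma (so that
    det(x_sigma, x_sigmasigma) = 1) and kappa = det(x_ss, x_sss) is
    evaluated on a uniform sigma grid, then mapped back to the original
    samples.  Parabolas give kappa = 0, ellipses with semi-axes (a, b)
    give (ab)**(-2/3), hyperbolas give negative values.  Spans where the
    equi-affine speed falls below ``sigma_floor`` (inflections, straight
    motion) are flagged undefined.

    Returns ``(kappa, defined)`` aligned to the trajectory samples.
    """
    if isinstance(traj, KinematicProfile):
        traj = traj.traj
    n = len(traj)
    if n < 4 * smooth_window:
        raise ValueError("span too short for third sigma-derivatives")
    prof = differentiate(traj, smooth_window)
    cross = prof.vx * prof.ay - prof.vy * prof.ax
    # Work in a consistent orientation: reflect if the curve is traversed
    # clockwise on average (reflection preserves |kappa| and the sign for
    # conics, which is set by the curve type).
    x, y = traj.x, traj.y
    if np.nanmedian(cross[prof.defined]) < 0:
        y = -y
        cross = -cross
    sdot = np.cbrt(np.clip(cross, 0.0, None))
    defined = prof.defined & (sdot > sigma_floor)
    kappa = np.full(n, np.nan)
    if defined.sum() < 4 * smooth_window:
        return kappa, np.zeros(n, dtype=bool)
    # Largest contiguous well-defined span.
    runs = _runs_of_true(defined)
    i0, i1 = max(runs, key=lambda r: r[1] - r[0])
    sl = slice(i0, i1)
    sigma = np.concatenate([[0.0], np.cumsum(0.5 * (sdot[sl][1:] + sdot[sl][:-1]) * traj.dt)])
    if n_sigma is None:
        n_sigma = max(4 * smooth_window, i1 - i0)
    s_grid = np.linspace(sigma[0], sigma[-1], n_sigma)
    # Strictly increasing sigma is guaranteed by the floor.
    csx = CubicSpline(sigma, x[sl])
    csy = CubicSpline(sigma, y[sl])
    ds = s_grid[1] - s_grid[0]
    w = min(smooth_window, (n_sigma - 1) | 1)
    xs = savgol_filter(csx(s_grid), w, 3, deriv=1, delta=ds)
    ys = savgol_filter(csy(s_grid), w, 3, deriv=1, delta=ds)
    xss = savgol_filter(csx(s_grid), w, 3, deriv=2, delta=ds)
    yss = savgol_filter(csy(s_grid), w, 3, deriv=2, delta=ds)
    xsss = savgol_filter(csx(s_grid), w, 3, deriv=3, delta=ds)
    ysss = savgol_filter(csy(s_grid), w, 3, deriv=3, delta=ds)
    # Renormalize: numerically det(x_s, x_ss) may drift from 1.
    det1 = xs * yss - ys * xss
    with np.errstate(invalid="ignore"):
        k_grid = (xss * ysss - yss * xsss) / np.where(det1 > 0, det1, np.nan) ** (5.0 / 3.0)
    # Trim the filter's edge samples on the sigma grid.
    edge = w
    k_grid[:edge] = np.nan
    k_grid[-edge:] = np.nan
    kappa[sl] = np.interp(sigma, s_grid, k_grid)
    out_def = np.zeros(n, dtype=bool)
    out_def[sl] = np.isfinite(kappa[sl])
    defined_out = defined & out_def
    kappa[~defined_out] = np.nan
    return kappa, defined_out


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(idx[i], idx[i + 1]) for i in range(0, len(idx), 2)]


def power_law_fit(profile: KinematicProfile, mask: np.ndarray | None = None,
                  v_floor: float = V_FLOOR, c_floor: float = C_FLOOR,
                  min_samples: int = 20) -> PowerLawFit:
    """Fit the power law A = K * C**beta by least squares in log-log space.

    Only samples with speed and curvature above the floors enter the fit.
    Rejects degenerate inputs (too few usable samples, or no curvature
    variation as on a perfect circle).
    """
    usable = profile.curvature_defined & (profile.speed > v_floor)
    usable &= np.nan_to_num(profile.curvature) > c_floor
    if mask is not None:
        usable &= mask
    n = int(usable.sum())
    if n < min_samples:
        raise ValueError(f"only {n} usable samples (need >= {min_samples})")
    logc = np.log(profile.curvature[usable])
    loga = np.log(profile.angular_speed[usable])
    if logc.std() < 1e-6:
        raise ValueError("no curvature variation; power-law exponent unidentifiable")
    beta, logk = np.polyfit(logc, loga, 1)
    resid = loga - (beta * logc + logk)
    ss_tot = float(np.sum((loga - loga.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(beta=float(beta), K=float(np.exp(logk)), r2=r2, n_samples=n)
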