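"""Multi-delay linear tuning of single-unit firing to kinematics.

Motor-cortical firing rates are modeled as a linear function of hand
position, velocity and acceleration, each entering at its own delay:

    lambda(t) = a.x(t+tau_x) + b.y(t+tau_y) + c.z(t+tau_z) + d

where x, y, z are the 2-D position, velocity and acceleration signals
(each contributing a 2-vector coefficient) and the three delays range
over +-250 ms.  Fitting every delay combination yields a cube of
goodness-of-fit values; because the three signals are correlated, the
*contribution* of one parameter is its delta-R^2 — the drop in R^2 when
the parameter is removed from the model with the other delays refit.
A stripe of the cube at a fixed delay of the target parameter is deemed
dominant when at least half its cells exceed max(R^2)/2.

The same machinery compares Euclidean vs. equi-affine speed as rate
regressors, f(t) = a + b*s_dot(t+tau_s) + c*sigma_dot(t+tau_sigma),
with dominance assessed per speed and significance by a circular-shift
permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .kinematics import KinematicProfile, Trajectory

__all__ = [
    "RateSeries",
    "DelayCube",
    "ContributionResult",
    "rate_estimate",
    "delay_regression_pva",
    "partial_contribution",
    "dominant_stripe",
    "speed_model_fit",
]


@dataclass
class RateSeries:
    t: np.ndarray
    rate: np.ndarray    # spikes/s

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class DelayCube:
    """R^2 (and optionally coefficients) over a complete delay grid."""

    delays: np.ndarray          # shared axis, s
    r2: np.ndarray              # (L, L, L) for pva or (L, L) for speeds
    names: tuple[str, ...]
    flagged: np.ndarray | None = None

    def best(self) -> tuple[tuple[float, ...], float]:
        idx = np.unravel_index(np.nanargmax(self.r2), self.r2.shape)
        return tuple(self.delays[i] for i in idx), float(self.r2[idx])


@dataclass
class ContributionResult:
    which: str
    values: np.ndarray          # contribution per delay combination
    dominant: bool
    dominant_lag: float | None


def rate_estimate(spike_times: np.ndarray, duration: float, bin: float = 0.01,
                  smooth: float = 0.025) -> RateSeries:
    """Binned spike counts / bin width, Gaussian-smoothed (sigma in s)."""
    T = int(np.ceil(duration / bin))
    edges = np.arange(T + 1) * bin
    counts, _ = np.histogram(spike_times, bins=edges)
    rate = counts / bin
    if smooth > 0:
        rate = gaussian_filter1d(rate.astype(float), smooth / bin)
    t = (edges[:-1] + edges[1:]) / 2
    return RateSeries(t=t, rate=rate)


def _lagged(sig: np.ndarray, lag: int) -> np.ndarray:
    """sig(t + lag) with edge replication; lag in samples."""
    out = np.empty_like(sig)
    if lag >= 0:
        out[:len(sig) - lag] = sig[lag:]
        out[len(sig) - lag:] = sig[-1]
    else:
        out[-lag:] = sig[:lag]
        out[:-lag] = sig[0]
    return out


class _GridFit:
    """Precomputed lagged regressors and Gram blocks for a delay grid.

    The Gram matrix of the lagged regressors does not depend on y, so
    it is assembled once (vectorized over all delay combinations) and
    reused — in particular across permutation surrogates.
    """

    def __init__(self, groups: list[np.ndarray], delays_idx: np.ndarray):
        self.ng = len(groups)
        self.dims = [g.shape[1] for g in groups]
        self.L = len(delays_idx)
        self.lagged = []   # per group: (L, T, d_g), centered
        for g in groups:
            cols = np.stack([np.column_stack([_lagged(g[:, j], k)
                                              for j in range(g.shape[1])])
                             for k in delays_idx])
            cols = cols - cols.mean(axis=1, keepdims=True)
            self.lagged.append(cols)
        o = np.cumsum([0] + self.dims)
        ptot = o[-1]
        shape = (self.L,) * self.ng
        ncell = self.L ** self.ng
        G = np.zeros(shape + (ptot, ptot))
        for gi in range(self.ng):
            # Diagonal block depends on one axis only.
            diag = np.einsum("ltd,lte->lde", self.lagged[gi], self.lagged[gi])
            # Broadcast the diagonal block over the other grid axes.
            idx = [np.newaxis] * self.ng
            idx[gi] = slice(None)
            G[..., o[gi]:o[gi + 1], o[gi]:o[gi + 1]] += diag[tuple(idx)]
            for hi in range(gi + 1, self.ng):
                blk = np.einsum("atd,bte->abde", self.lagged[gi], self.lagged[hi])
                idx2 = [np.newaxis] * self.ng
                idx2[gi] = slice(None)
                idx2[hi] = slice(None)
                # blk axes (a, b) map to grid axes (gi, hi).
                expand = blk
                for ax in range(self.ng):
                    if ax != gi and ax != hi:
                        expand = np.expand_dims(expand, axis=ax)
                G[..., o[gi]:o[gi + 1], o[hi]:o[hi + 1]] += expand
                G[..., o[hi]:o[hi + 1], o[gi]:o[gi + 1]] += np.swapaxes(expand, -1, -2)
        tr = np.trace(G, axis1=-2, axis2=-1)[..., None, None]
        G = G + 1e-10 * tr / ptot * np.eye(ptot)
        self.G = G.reshape(ncell, ptot, ptot)
        self.offsets = o
        self.shape = shape
        self.ptot = ptot

    def r2(self, y: np.ndarray):
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot <= 0:
            return np.zeros(self.shape), np.ones(self.shape, dtype=bool)
        o = self.offsets
        v = np.zeros(self.shape + (self.ptot,))
        for gi in range(self.ng):
            xty = np.einsum("ltd,t->ld", self.lagged[gi], yc)   # (L, d)
            idx = [np.newaxis] * self.ng
            idx[gi] = slice(None)
            v[..., o[gi]:o[gi + 1]] += xty[tuple(idx)]
        vf = v.reshape(-1, self.ptot)
        try:
            beta = np.linalg.solve(self.G, vf[..., None])[..., 0]
            flagged = np.zeros(self.shape, dtype=bool)
        except np.linalg.LinAlgError:
            beta = np.stack([np.linalg.lstsq(Gc, vc, rcond=None)[0]
                             for Gc, vc in zip(self.G, vf)])
            flagged = np.zeros(self.shape, dtype=bool)
        expl = np.einsum("cp,cp->c", beta, vf) / ss_tot
        return np.clip(expl.reshape(self.shape), 0.0, 1.0), flagged


def _grid_r2(y: np.ndarray, groups: list[np.ndarray], delays_idx: np.ndarray):
    """R^2 of y ~ intercept + lagged groups at every delay combination."""
    return _GridFit(groups, delays_idx).r2(y)


def _resample_to(rate: RateSeries, t_kin: np.ndarray) -> np.ndarray:
    return np.interp(t_kin, rate.t, rate.rate)


def delay_regression_pva(rate: RateSeries, traj: Trajectory,
                         profile: KinematicProfile,
                         max_delay: float = 0.25, step: float = 0.01
                         ) -> DelayCube:
    """Fit the three-delay position/velocity/acceleration model on a grid.

    Each of the three signals is 2-D (x and y components), so the model
    has 7 free parameters per cell (3 x 2 coefficients + intercept).
    R^2 per cell is computed in closed form; scoring of the best cell
    respects the non-negativity of rates by clipping predictions at 0.
    """
    y = _resample_to(rate, traj.t)
    if traj.duration < 60:
        raise ValueError("need at least 60 s of usable overlap")
    pos = np.column_stack([traj.x - traj.x.mean(), traj.y - traj.y.mean()])
    vel = np.column_stack([profile.vx, profile.vy])
    acc = np.column_stack([profile.ax, profile.ay])
    step_samples = max(1, int(round(step / traj.dt)))
    max_lag = int(round(max_delay / traj.dt))
    delays_idx = np.arange(-max_lag, max_lag + 1, step_samples)
    r2, flagged = _grid_r2(y, [pos, vel, acc], delays_idx)
    return DelayCube(delays=delays_idx * traj.dt, r2=r2,
                     names=("position", "velocity", "acceleration"),
                     flagged=flagged)


def _reduced_grid(y, groups, delays_idx, drop: int):
    keep = [g for i, g in enumerate(groups) if i != drop]
    r2, _ = _grid_r2(y, keep, delays_idx)
    return r2


def partial_contribution(rate: RateSeries, traj: Trajectory,
                         profile: KinematicProfile, which: str,
                         cube: DelayCube | None = None,
                         max_delay: float = 0.25, step: float = 0.01
                         ) -> ContributionResult:
    """Delta-R^2 contribution of one parameter given the other two.

    contribution(tau) = R^2(full at tau) - R^2(model without the target,
    other delays matched); by nesting this is non-negative.  Dominance
    of a target-delay stripe follows the half-above-half-max rule.
    """
    names = ("position", "velocity", "acceleration")
    if which not in names:
        raise ValueError(f"which must be one of {names}")
    axis = names.index(which)
    y = _resample_to(rate, traj.t)
    pos = np.column_stack([traj.x - traj.x.mean(), traj.y - traj.y.mean()])
    vel = np.column_stack([profile.vx, profile.vy])
    acc = np.column_stack([profile.ax, profile.ay])
    groups = [pos, vel, acc]
    step_samples = max(1, int(round(step / traj.dt)))
    max_lag = int(round(max_delay / traj.dt))
    delays_idx = np.arange(-max_lag, max_lag + 1, step_samples)
    if cube is None:
        r2_full, _ = _grid_r2(y, groups, delays_idx)
    else:
        r2_full = cube.r2
    r2_red = _reduced_grid(y, groups, delays_idx, axis)   # (L, L) over the others
    shape_red = [slice(None)] * 3
    shape_red[axis] = None
    red_b = np.expand_dims(r2_red, axis=axis)
    contrib = np.maximum(r2_full - red_b, 0.0)
    # Collapse to a stripe profile: contribution per target delay with the
    # other two at the stripe's cells.
    dom, lag = dominant_stripe(contrib, axis=axis,
                               delays=delays_idx * traj.dt)
    return ContributionResult(which=which, values=contrib, dominant=dom,
                              dominant_lag=lag)


def dominant_stripe(values: np.ndarray, axis: int = 0,
                    delays: np.ndarray | None = None,
                    threshold: float | None = None) -> tuple[bool, float | None]:
    """Half-above-half-max dominance rule over a delay grid.

    A stripe (one fixed delay of the target axis, all combinations of
    the other delays) is dominant iff at least 50% of its cells exceed
    max(values)/2.  Among qualifying stripes the one with the highest
    mean wins; ties go to the smaller absolute lag.  Returns
    (dominant, best_lag) with lags taken from ``delays`` (or the axis
    index when delays are not given).
    """
    vmax = np.nanmax(values)
    if threshold is None:
        threshold = vmax / 2.0
    if not np.isfinite(vmax) or vmax <= 0:
        return False, None
    moved = np.moveaxis(values, axis, 0)
    L = moved.shape[0]
    flat = moved.reshape(L, -1)
    frac_above = (flat > threshold).mean(axis=1)
    qual = frac_above >= 0.5
    if not qual.any():
        return False, None
    means = np.where(qual, flat.mean(axis=1), -np.inf)
    lags = delays if delays is not None else np.arange(L).astype(float)
    best = np.flatnonzero(means == means.max())
    i = best[np.argmin(np.abs(lags[best]))]
    return True, float(lags[i])


def speed_model_fit(rate: RateSeries, traj: Trajectory, profile: KinematicProfile,
                    max_delay: float = 0.25, step: float = 0.01,
                    n_perm: int = 200, min_shift: float = 5.0,
                    seed: int = 0) -> dict:
    """Euclidean vs. equi-affine speed as competing rate regressors.

    Fits f(t) = a + b*s_dot(t+tau_s) + c*sigma_dot(t+tau_sigma) over the
    delay grid; reports per-speed contribution matrices as fractions of
    the total R^2, stripe dominance for each speed, and a circular-shift
    permutation p-value for the model (shifts of at least ``min_shift``
    seconds preserve the rate's autocorrelation).
    """
    y = _resample_to(rate, traj.t)
    s_dot = profile.speed[:, None]
    sigma_dot = profile.ea_speed[:, None]
    corr = np.corrcoef(s_dot[:, 0], sigma_dot[:, 0])[0, 1]
    step_samples = max(1, int(round(step / traj.dt)))
    max_lag = int(round(max_delay / traj.dt))
    delays_idx = np.arange(-max_lag, max_lag + 1, step_samples)
    delays = delays_idx * traj.dt
    fit_full = _GridFit([s_dot, sigma_dot], delays_idx)
    r2_full, _ = fit_full.r2(y)
    r2_s, _ = _grid_r2(y, [s_dot], delays_idx)        # (L,)
    r2_sig, _ = _grid_r2(y, [sigma_dot], delays_idx)  # (L,)
    total = float(np.nanmax(r2_full))
    contrib_s = np.maximum(r2_full - r2_sig[None, :], 0.0)      # drop s_dot -> sigma only
    contrib_sig = np.maximum(r2_full - r2_s[:, None], 0.0)
    if total > 0:
        frac_s = contrib_s / total
        frac_sig = contrib_sig / total
    else:
        frac_s, frac_sig = contrib_s, contrib_sig
    if corr > 0.999:
        verdict = "indistinguishable"
        dom_s = dom_sig = (False, None)
    else:
        dom_s = dominant_stripe(contrib_s, axis=0, delays=delays)
        dom_sig = dominant_stripe(contrib_sig, axis=1, delays=delays)
        if dom_sig[0] and not dom_s[0]:
            verdict = "equi-affine"
        elif dom_s[0] and not dom_sig[0]:
            verdict = "euclidean"
        elif dom_s[0] and dom_sig[0]:
            verdict = "both"
        else:
            verdict = "neither"
    # Permutation test: circular shifts of the rate.
    rng = np.random.default_rng(seed)
    T = len(y)
    min_shift_samples = int(round(min_shift / traj.dt))
    null = np.empty(n_perm)
    for i in range(n_perm):
        sh = rng.integers(min_shift_samples, T - min_shift_samples)
        y_sh = np.roll(y, sh)
        r2p, _ = fit_full.r2(y_sh)
        null[i] = np.nanmax(r2p)
    p = float((np.sum(null >= total) + 1) / (n_perm + 1))
    return {
        "delays": delays,
        "r2": r2_full,
        "contribution_euclid": frac_s,
        "contribution_ea": frac_sig,
        "euclid_dominant": dom_s[0], "euclid_lag": dom_s[1],
        "ea_dominant": dom_sig[0], "ea_lag": dom_sig[1],
        "verdict": verdict,
        "p_value": p,
        "total_r2": total,
        "speed_correlation": float(corr),
    }
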