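"""Hidden-state analysis of parallel spike trains.

A small patch of motor cortex is modeled as an N-state first-order
Markov chain whose observable output is the spiking of the M recorded
units: within a state the units fire as independent Poisson processes
with state-specific rates, so the probability of observing n spikes of
one unit in a bin of width dt is e^(-x) x^n / n! with x = lambda*dt.
Because rates are low the bins must be fairly wide (50 ms default).

The likelihood terrain is rough, so the EM initialization matters.  It
follows a change-point recipe: per bin and unit, the minus-log-likelihood
(MLL) that the current count arose from the rate seen over the trailing
200 ms is computed and summed over units; prominent MLL peaks mark
coordinated rate flips; segment mean-rate vectors are k-means-clustered
into N groups from which the transition and rate matrices are seeded.
Baum-Welch (soft EM) and Viterbi training (hard EM) refine the model;
states are deemed *dominant* over a stretch when their posterior exceeds
0.5 for at least 0.1 s with a time-average of at least 0.75, and each
state's dominant periods can be aligned to the concurrent movement by a
single best time lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks
from scipy.special import gammaln, logsumexp
from sklearn.cluster import KMeans

from .kinematics import Trajectory, differentiate

__all__ = [
    "SpikeTrainSet",
    "CountMatrix",
    "HmmModel",
    "StateTrace",
    "bin_spikes",
    "mll_changepoints",
    "init_hmm",
    "baum_welch",
    "viterbi_train",
    "viterbi_path",
    "dominant_states",
    "align_states_to_movement",
    "match_states",
]

REFRACTORY_FLOOR = 1e-3  # s


@dataclass
class SpikeTrainSet:
    """Parallel spike trains: per-unit sorted spike times with electrode labels."""

    units: list[dict]  # each {unit_id, electrode_id, spike_times: np.ndarray}
    duration: float

    def __post_init__(self):
        for u in self.units:
            st = np.asarray(u["spike_times"], dtype=float)
            if st.size and (st.min() < 0 or st.max() > self.duration + 1e-9):
                raise ValueError(f"unit {u['unit_id']}: spikes outside [0, duration]")
            if st.size > 1 and np.diff(st).min() < 0:
                st = np.sort(st)
                warnings.warn(f"unit {u['unit_id']}: spike times were unsorted")
            u["spike_times"] = st

    @property
    def n_units(self) -> int:
        return len(self.units)

    def spike_times(self, i: int) -> np.ndarray:
        return self.units[i]["spike_times"]

    def electrode(self, i: int) -> object:
        return self.units[i]["electrode_id"]


@dataclass
class CountMatrix:
    counts: np.ndarray  # (T, M) nonnegative ints
    dt: float
    t0: float = 0.0

    @property
    def T(self) -> int:
        return self.counts.shape[0]

    @property
    def M(self) -> int:
        return self.counts.shape[1]

    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.T) + 0.5) * self.dt


@dataclass
class HmmModel:
    P: np.ndarray        # (N, N) row-stochastic transitions
    Lambda: np.ndarray   # (N, M) rates, spikes/s
    pi: np.ndarray       # (N,) initial distribution
    dt: float
    log_likelihood: float = np.nan

    @property
    def N(self) -> int:
        return self.P.shape[0]

    def validate(self):
        if np.abs(self.P.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("transition rows must sum to 1")
        if not np.isfinite(self.Lambda).all() or (self.Lambda < 0).any():
            raise ValueError("rates must be finite and nonnegative")


@dataclass
class StateTrace:
    posterior: np.ndarray          # (T, N)
    viterbi_path: np.ndarray       # (T,)
    dt: float
    t0: float = 0.0
    dominant_periods: list[dict] = field(default_factory=list)


def bin_spikes(spikes: SpikeTrainSet, dt: float = 0.05) -> CountMatrix:
    """Count spikes in half-open bins [k*dt, (k+1)*dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = int(np.ceil(spikes.duration / dt - 1e-9))
    T = max(T, 1)
    edges = np.arange(T + 1) * dt
    counts = np.zeros((T, spikes.n_units), dtype=int)
    for j in range(spikes.n_units):
        idx = np.searchsorted(edges, spikes.spike_times(j), side="right") - 1
        idx = idx[(idx >= 0) & (idx < T)]
        np.add.at(counts[:, j], idx, 1)
    return CountMatrix(counts=counts, dt=dt)


def mll_changepoints(counts: CountMatrix, history: float = 0.2,
                     mode: str = "sd", sd_factor: float = 5.0,
                     top_fraction: float = 0.22,
                     pseudo_count: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Coordinated rate-flip times from the summed minus-log-likelihood trace.

    For each bin and unit, MLL_i = -log P(count now | Poisson rate fit to
    the trailing ``history`` seconds); MLL = sum_i MLL_i.  Peaks above
    ``sd_factor`` standard deviations (mode 'sd') or the top
    ``top_fraction`` of peaks (mode 'top_fraction') are returned as
    transition times (bin-edge seconds).  Returns (times, mll_series).
    """
    h = int(round(history / counts.dt))
    if abs(h * counts.dt - history) > 1e-9:
        raise ValueError("history must be a multiple of dt")
    if counts.T <= h:
        raise ValueError("record shorter than the history window")
    C = counts.counts.astype(float)
    csum = np.cumsum(np.vstack([np.zeros(C.shape[1]), C]), axis=0)
    hist_counts = csum[h:-1] - csum[:-h - 1]          # counts in trailing window
    x = (hist_counts + pseudo_count) / h              # expected count per bin
    n = C[h:]
    mll_i = x - n * np.log(x) + gammaln(n + 1.0)
    mll = mll_i.sum(axis=1)
    if np.ptp(mll) == 0:
        return np.array([]), mll
    peaks, props = find_peaks(mll, prominence=1e-9)
    if len(peaks) == 0:
        return np.array([]), mll
    if mode == "sd":
        thr = mll.mean() + sd_factor * mll.std()
        keep = peaks[mll[peaks] > thr]
    elif mode == "top_fraction":
        k = max(1, int(round(top_fraction * len(peaks))))
        keep = peaks[np.argsort(mll[peaks])[::-1][:k]]
        keep = np.sort(keep)
    else:
        raise ValueError("mode must be 'sd' or 'top_fraction'")
    times = counts.t0 + (keep + h) * counts.dt
    return times, mll


def init_hmm(counts: CountMatrix, changepoints: np.ndarray, N: int,
             seed: int = 0) -> HmmModel:
    """Initial (P, Lambda) from inter-changepoint segments.

    Segment mean-rate vectors are clustered into N groups by k-means;
    transition probabilities come from add-one-smoothed segment-label
    bigrams; rates pool all bins assigned to a group.
    """
    edges = np.concatenate([[0], np.round((np.asarray(changepoints) - counts.t0)
                                          / counts.dt).astype(int), [counts.T]])
    edges = np.unique(np.clip(edges, 0, counts.T))
    segs = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]
    if len(segs) < N:
        raise ValueError(f"only {len(segs)} segments for {N} states")
    rates = np.array([counts.counts[a:b].mean(axis=0) / counts.dt for a, b in segs])
    km = KMeans(n_clusters=N, n_init=10, random_state=seed).fit(rates)
    labels = km.labels_
    P0 = np.ones((N, N))  # add-one smoothing
    for a, b in zip(labels[:-1], labels[1:]):
        P0[a, b] += 1
    P0 /= P0.sum(axis=1, keepdims=True)
    Lam0 = np.zeros((N, counts.M))
    for k in range(N):
        sel = np.zeros(counts.T, dtype=bool)
        for (a, b), l in zip(segs, labels):
            if l == k:
                sel[a:b] = True
        Lam0[k] = counts.counts[sel].mean(axis=0) / counts.dt if sel.any() else rates.mean(axis=0)
    pi = np.full(N, 1.0 / N)
    return HmmModel(P=P0, Lambda=np.maximum(Lam0, 1e-3), pi=pi, dt=counts.dt)


def _log_emission(counts: CountMatrix, Lambda: np.ndarray) -> np.ndarray:
    """(T, N) log product-Poisson emission probabilities."""
    x = np.maximum(Lambda * counts.dt, 1e-12)       # (N, M) expected counts
    n = counts.counts                                # (T, M)
    ll = n @ np.log(x).T - x.sum(axis=1)[None, :] - gammaln(n + 1.0).sum(axis=1)[:, None]
    return ll


def _forward_backward(logB: np.ndarray, P: np.ndarray, pi: np.ndarray):
    T, N = logB.shape
    logP = np.log(np.maximum(P, 1e-300))
    la = np.zeros((T, N))
    la[0] = np.log(np.maximum(pi, 1e-300)) + logB[0]
    for t in range(1, T):
        la[t] = logB[t] + logsumexp(la[t - 1][:, None] + logP, axis=0)
    lb = np.zeros((T, N))
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(logP + (logB[t + 1] + lb[t + 1])[None, :], axis=1)
    ll = float(logsumexp(la[-1]))
    post = np.exp(la + lb - ll)
    post /= post.sum(axis=1, keepdims=True)
    return la, lb, post, ll


def baum_welch(counts: CountMatrix, init: HmmModel, max_iter: int = 500,
               tol: float = 1e-6) -> tuple[HmmModel, StateTrace]:
    """Soft EM on the product-Poisson HMM.

    The per-bin log-likelihood is monotone non-decreasing; iteration
    stops when its increment falls below ``tol`` nats/bin.
    """
    init.validate()
    P, Lam, pi = init.P.copy(), init.Lambda.copy(), init.pi.copy()
    T = counts.T
    prev_ll = -np.inf
    for _ in range(max_iter):
        logB = _log_emission(counts, Lam)
        la, lb, post, ll = _forward_backward(logB, P, pi)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood during EM")
        logP = np.log(np.maximum(P, 1e-300))
        # Expected transitions.
        xi = np.zeros_like(P)
        for t in range(T - 1):
            m = la[t][:, None] + logP + (logB[t + 1] + lb[t + 1])[None, :] - ll
            xi += np.exp(m)
        P = xi + 1e-12
        P /= P.sum(axis=1, keepdims=True)
        w = post.sum(axis=0)                           # (N,)
        Lam = (post.T @ counts.counts) / np.maximum(w[:, None], 1e-12) / counts.dt
        Lam = np.maximum(Lam, 1e-6)
        pi = np.maximum(post[0], 1e-12)
        pi /= pi.sum()
        if (ll - prev_ll) / T < tol:
            prev_ll = ll
            break
        prev_ll = ll
    model = HmmModel(P=P, Lambda=Lam, pi=pi, dt=counts.dt, log_likelihood=prev_ll)
    logB = _log_emission(counts, Lam)
    _, _, post, ll = _forward_backward(logB, P, pi)
    path = viterbi_path(counts, model)
    return model, StateTrace(posterior=post, viterbi_path=path, dt=counts.dt, t0=counts.t0)


def viterbi_path(counts: CountMatrix, model: HmmModel) -> np.ndarray:
    logB = _log_emission(counts, model.Lambda)
    logP = np.log(np.maximum(model.P, 1e-300))
    T, N = logB.shape
    delta = np.log(np.maximum(model.pi, 1e-300)) + logB[0]
    back = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        m = delta[:, None] + logP
        back[t] = np.argmax(m, axis=0)
        delta = logB[t] + np.max(m, axis=0)
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def viterbi_train(counts: CountMatrix, init: HmmModel, max_iter: int = 200,
                  tol: float = 1e-6, seed: int = 0) -> tuple[HmmModel, np.ndarray]:
    """Hard-assignment EM: refit (P, Lambda) from the current Viterbi path.

    Empty states are re-seeded by splitting the most-populated state.
    """
    init.validate()
    rng = np.random.default_rng(seed)
    P, Lam, pi = init.P.copy(), init.Lambda.copy(), init.pi.copy()
    N = init.N
    prev_score = -np.inf
    path = None
    for _ in range(max_iter):
        model = HmmModel(P=P, Lambda=Lam, pi=pi, dt=counts.dt)
        path = viterbi_path(counts, model)
        occupied, occ_counts = np.unique(path, return_counts=True)
        for k in range(N):
            if k not in occupied:
                big = occupied[np.argmax(occ_counts)]
                Lam[k] = Lam[big] * np.exp(rng.normal(0, 0.1, counts.M))
        P_new = np.ones((N, N))
        for a, b in zip(path[:-1], path[1:]):
            P_new[a, b] += 1
        P_new /= P_new.sum(axis=1, keepdims=True)
        Lam_new = Lam.copy()
        for k in range(N):
            sel = path == k
            if sel.any():
                Lam_new[k] = np.maximum(counts.counts[sel].mean(axis=0) / counts.dt, 1e-6)
        pi_new = np.full(N, 1e-12)
        pi_new[path[0]] = 1.0
        pi_new /= pi_new.sum()
        logB = _log_emission(counts, Lam_new)
        score = float(logB[np.arange(counts.T), path].sum())
        P, Lam, pi = P_new, Lam_new, pi_new
        if score - prev_score < tol * counts.T and np.isfinite(prev_score):
            prev_score = score
            break
        prev_score = score
    model = HmmModel(P=P, Lambda=Lam, pi=pi, dt=counts.dt, log_likelihood=prev_score)
    return model, path


def dominant_states(trace: StateTrace, p_min: float = 0.5, min_dur: float = 0.1,
                    avg_min: float = 0.75) -> list[dict]:
    """Maximal posterior runs meeting the dominance rule.

    A state is dominant over a period when its posterior stays above
    ``p_min`` for at least ``min_dur`` seconds and its time-average over
    the period is at least ``avg_min``.  Elsewhere the system is in an
    'unknown' state.
    """
    T, N = trace.posterior.shape
    periods = []
    best = np.argmax(trace.posterior, axis=1)
    above = trace.posterior[np.arange(T), best] > p_min
    t = 0
    while t < T:
        if not above[t]:
            t += 1
            continue
        s = best[t]
        u = t
        while u < T and above[u] and best[u] == s:
            u += 1
        dur = (u - t) * trace.dt
        avg = trace.posterior[t:u, s].mean()
        if dur >= min_dur and avg >= avg_min:
            periods.append({"state": int(s),
                            "t_start": trace.t0 + t * trace.dt,
                            "t_end": trace.t0 + u * trace.dt})
        t = u
    trace.dominant_periods = periods
    return periods


# ---------------------------------------------------------------------------
# Alignment of dominant states to movement


def _tangent_profile(traj: Trajectory, t_start: float, t_end: float,
                     n_points: int = 20) -> np.ndarray | None:
    """Length-normalized tangent-angle profile of a movement segment."""
    i0 = int(np.searchsorted(traj.t, t_start))
    i1 = int(np.searchsorted(traj.t, t_end))
    if i1 - i0 < 4:
        return None
    x, y = traj.x[i0:i1], traj.y[i0:i1]
    dx, dy = np.diff(x), np.diff(y)
    seg = np.hypot(dx, dy)
    L = seg.sum()
    if L <= 0:
        return None
    s = np.concatenate([[0], np.cumsum(seg)]) / L
    ang = np.unwrap(np.arctan2(dy, dx))
    smid = 0.5 * (s[:-1] + s[1:])
    grid = np.linspace(smid[0], smid[-1], n_points)
    return np.interp(grid, smid, ang)


def align_states_to_movement(periods: list[dict], traj: Trajectory,
                             lag_grid: np.ndarray | None = None) -> dict:
    """Best per-state lag between neural dominance and movement shape.

    For each state, the movement segments concurrent with its dominant
    periods, shifted by a candidate lag, are compared pairwise by the
    RMS difference of their length-normalized tangent-angle profiles
    (rotation-sensitive, since states are orientation-specific); the lag
    minimizing the mean dissimilarity wins.  Positive lag means the
    neural state leads the movement.
    """
    if lag_grid is None:
        lag_grid = np.arange(-0.2, 0.2001, 0.01)
    states = sorted({p["state"] for p in periods})
    out = {}
    for s in states:
        ps = [p for p in periods if p["state"] == s]
        if len(ps) < 2:
            out[s] = {"lag": None, "dissimilarity": None, "flag": "fewer than 2 periods"}
            continue
        best_lag, best_d, curve = None, np.inf, []
        for lag in lag_grid:
            profiles = []
            for p in ps:
                prof = _tangent_profile(traj, p["t_start"] + lag, p["t_end"] + lag)
                if prof is not None:
                    profiles.append(prof)
            if len(profiles) < 2:
                curve.append(np.nan)
                continue
            dsum, npair = 0.0, 0
            for i in range(len(profiles)):
                for j in range(i + 1, len(profiles)):
                    dsum += np.sqrt(np.mean((profiles[i] - profiles[j]) ** 2))
                    npair += 1
            d = dsum / npair
            curve.append(d)
            if d < best_d:
                best_lag, best_d = float(lag), d
        out[s] = {"lag": best_lag, "dissimilarity": best_d,
                  "lag_grid": np.asarray(lag_grid), "curve": np.asarray(curve)}
    return out


def match_states(Lambda_est: np.ndarray, Lambda_true: np.ndarray) -> np.ndarray:
    """Hungarian assignment of estimated to true states by rate-vector distance.

    Returns ``perm`` such that estimated state ``perm[k]`` corresponds to
    true state ``k``.
    """
    cost = np.linalg.norm(Lambda_true[:, None, :] - Lambda_est[None, :, :], axis=2)
    r, c = linear_sum_assignment(cost)
    perm = np.zeros(len(r), dtype=int)
    perm[r] = c
    return perm
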