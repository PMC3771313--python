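"""Synthetic data with the statistical structure the analyses assume.

Every stage of the pipeline is exercised on generated data with known
ground truth: scribbles built from parabolic segments traversed at
constant equi-affine speed (hence obeying the two-thirds power law),
spike trains that are inhomogeneous-Poisson with linear kinematic tuning
at unit-specific delays, Markov-modulated population activity, precise
cross-unit spike intervals planted around drawing events, and to-and-fro
scanning trajectories following a strokelet grammar.  Each generator
returns a machine-readable truth ledger and is reproducible bit-for-bit
given (spec, seed).

Parabolic segments are built in velocity space: a segment is a constant
acceleration, i.e. uniform motion along a straight arrow from velocity
v0 to v1, which integrates to a parabola in position space.  Successive
arrows share endpoints, so segments join tangent-continuously.  For an
arrow with |v x a| = xi and |a| = A the generated parabola has focal
parameter p = xi^2 / A^3 and equi-affine speed K = xi^(1/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import Trajectory
from .spikehmm import REFRACTORY_FLOOR, SpikeTrainSet

__all__ = [
    "ScribbleSpec",
    "TuningSpec",
    "PlantSpec",
    "velocity_cycle_spec",
    "gen_parabolic_scribble",
    "gen_tuned_spike_trains",
    "gen_markov_spike_trains",
    "embed_precise_patterns",
    "gen_syntax_trajectory",
    "gen_poisson_trains",
]


@dataclass
class ScribbleSpec:
    """Parabolic-scribble recipe: a cyclic graph of velocity-space arrows.

    ``waypoints`` are velocity-space vertices (mm/s); the scribble walks
    arrow i -> i+1 -> ... cyclically, each arrow traversed at constant
    acceleration over ``segment_duration`` seconds.  ``noise_sd`` is
    additive Gaussian position noise in mm.
    """

    waypoints: np.ndarray                  # (n, 2) velocity-space vertices
    segment_duration: float = 0.5          # s per parabolic segment
    n_segments: int = 12
    noise_sd: float = 0.0
    waypoint_jitter: float = 0.0           # mm/s sd on each visited vertex
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        if self.waypoints.ndim != 2 or self.waypoints.shape[1] != 2:
            raise ValueError("waypoints must be (n, 2)")
        if len(self.waypoints) < 2:
            raise ValueError("need at least 2 velocity waypoints")


def velocity_cycle_spec(n_classes: int = 3, speed: float = 300.0,
                        radii: np.ndarray | None = None,
                        **kwargs) -> ScribbleSpec:
    """A closed polygon of velocity arrows giving ``n_classes`` distinct
    parabola classes (distinct orientations) per cycle.

    ``speed`` sets the scale of the velocity waypoints (mm/s); the
    median hand speed in well-trained scribbling is around 300 mm/s.
    ``radii`` (relative per-vertex factors) makes the polygon irregular,
    which gives segments distinct equi-affine speeds — real scribbling
    has a piecewise-constant velocity gain that differs across strokes.
    """
    ang = 2 * np.pi * np.arange(n_classes) / n_classes + np.pi / n_classes
    r = np.ones(n_classes) if radii is None else np.asarray(radii, dtype=float)
    pts = speed * r[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
    return ScribbleSpec(waypoints=pts, **kwargs)


def _parabola_truth(v0: np.ndarray, v1: np.ndarray, T: float) -> dict:
    a = (v1 - v0) / T
    xi = abs(float(v0[0] * a[1] - v0[1] * a[0]))
    A = float(np.hypot(*a))
    if A == 0 or xi == 0:
        return {"p": np.nan, "orientation": np.nan, "K": 0.0}
    p = xi**2 / A**3
    n_hat = -a / A  # outward normal at the vertex is opposite the acceleration
    orientation = float(np.degrees(np.arctan2(n_hat[1], n_hat[0])) % 360.0)
    return {"p": p, "orientation": orientation, "K": xi ** (1.0 / 3.0)}


def gen_parabolic_scribble(spec: ScribbleSpec) -> tuple[Trajectory, dict]:
    """Generate a scribble of concatenated parabolic segments.

    Returns (trajectory, truth) where truth holds per-sample segment
    labels and the (p, orientation, K) of each segment class.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate
    n_per = int(round(spec.segment_duration / dt))
    if n_per < 2:
        raise ValueError("segment_duration too short for the sample rate")
    nw = len(spec.waypoints)
    # Visited vertices: the nominal cycle, optionally jittered per visit
    # (segment continuity is preserved because consecutive segments share
    # their visited vertex).
    visited = np.array([spec.waypoints[k % nw] for k in range(spec.n_segments + 1)])
    if spec.waypoint_jitter > 0:
        visited = visited + rng.normal(0.0, spec.waypoint_jitter, visited.shape)
    vel_rows, labels, seg_truth = [], [], []
    for k in range(spec.n_segments):
        v0 = visited[k]
        v1 = visited[k + 1]
        frac = np.arange(n_per) / n_per
        vel_rows.append(v0[None, :] + (v1 - v0)[None, :] * frac[:, None])
        labels.append(np.full(n_per, k))
        tr = _parabola_truth(v0, v1, spec.segment_duration)
        tr.update({"segment": k, "class": k % nw,
                   "t_start": k * spec.segment_duration,
                   "t_end": (k + 1) * spec.segment_duration})
        seg_truth.append(tr)
    vel = np.vstack(vel_rows)
    t = np.arange(len(vel)) * dt
    pos = np.vstack([[0.0, 0.0], np.cumsum(0.5 * (vel[1:] + vel[:-1]) * dt, axis=0)])
    pos = pos[:len(vel)]
    if spec.noise_sd > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd, pos.shape)
    traj = Trajectory(t, pos[:, 0], pos[:, 1])
    truth = {"labels": np.concatenate(labels), "segments": seg_truth,
             "n_classes": nw, "seed": spec.seed}
    return traj, truth


# ---------------------------------------------------------------------------
# Tuned spike trains (linear kinematic tuning at unit-specific delays)


@dataclass
class TuningSpec:
    """Per-unit linear tuning of firing rate to lagged kinematic signals.

    Each unit dict may specify: baseline (spikes/s), electrode_id, and
    coefficient/delay pairs for any of 'position', 'velocity',
    'acceleration' (2-vector coefficients, spikes/s per unit signal) or
    'euclid_speed' / 'ea_speed' (scalar coefficients).  Delays in
    seconds; positive delay means the rate leads the kinematics.
    """

    units: list[dict] = field(default_factory=list)


def _shift(sig: np.ndarray, lag_samples: int) -> np.ndarray:
    """sig(t + lag): positive lag pulls future values back to t."""
    out = np.empty_like(sig)
    if lag_samples >= 0:
        out[:len(sig) - lag_samples] = sig[lag_samples:]
        out[len(sig) - lag_samples:] = sig[-1]
    else:
        out[-lag_samples:] = sig[:lag_samples]
        out[:-lag_samples] = sig[0]
    return out


def gen_tuned_spike_trains(traj: Trajectory, spec: TuningSpec,
                           seed: int = 0, smooth_window: int = 11) -> tuple[SpikeTrainSet, dict]:
    """Inhomogeneous-Poisson spikes with rate = clip(linear tuning, 0).

    Sampling is by thinning of a homogeneous process at the rate
    ceiling; the truth ledger echoes coefficients and delays per unit.
    """
    from .kinematics import differentiate

    rng = np.random.default_rng(seed)
    prof = differentiate(traj, smooth_window)
    dt = traj.dt
    signals = {
        "position": np.column_stack([traj.x - traj.x.mean(), traj.y - traj.y.mean()]),
        "velocity": np.column_stack([prof.vx, prof.vy]),
        "acceleration": np.column_stack([prof.ax, prof.ay]),
        "euclid_speed": prof.speed[:, None],
        "ea_speed": prof.ea_speed[:, None],
    }
    units, truth_units = [], []
    for i, u in enumerate(spec.units):
        rate = np.full(len(traj), float(u.get("baseline", 5.0)))
        for name, sig in signals.items():
            if name not in u:
                continue
            coef = np.atleast_1d(np.asarray(u[name], dtype=float))
            delay = float(u.get(f"{name}_delay", 0.0))
            lag = int(round(delay / dt))
            shifted = np.column_stack([_shift(sig[:, j], lag) for j in range(sig.shape[1])])
            rate = rate + shifted @ coef
        clipped = np.clip(rate, 0.0, None)
        if (rate < 0).mean() > 0.5:
            import warnings
            warnings.warn(f"unit {i}: rate clipped >50% of the time; weakly identified")
        rmax = clipped.max()
        spikes = np.array([])
        if rmax > 0:
            n_cand = rng.poisson(rmax * traj.duration)
            cand = np.sort(rng.uniform(traj.t[0], traj.t[-1], n_cand))
            lam = np.interp(cand, traj.t, clipped)
            keep = rng.uniform(0, rmax, n_cand) < lam
            spikes = cand[keep]
            # Enforce the refractory floor by dropping offenders.
            if len(spikes) > 1:
                ok = np.concatenate([[True], np.diff(spikes) >= REFRACTORY_FLOOR])
                spikes = spikes[ok]
        units.append({"unit_id": i, "electrode_id": u.get("electrode_id", i),
                      "spike_times": spikes - traj.t[0]})
        truth_units.append({k: v for k, v in u.items()})
    sts = SpikeTrainSet(units=units, duration=traj.duration)
    return sts, {"units": truth_units, "seed": seed}


# ---------------------------------------------------------------------------
# Markov-modulated population spike trains


def gen_markov_spike_trains(N: int, M: int, P: np.ndarray, Lambda: np.ndarray,
                            duration: float, dt: float = 0.05,
                            seed: int = 0, pi: np.ndarray | None = None
                            ) -> tuple[SpikeTrainSet, np.ndarray]:
    """Exact discrete-time simulation of the Markov-modulated Poisson model.

    Returns (spike trains, true state path per bin).  Spike times are
    placed uniformly within their bin, thinned to the refractory floor.
    """
    P = np.asarray(P, dtype=float)
    Lambda = np.asarray(Lambda, dtype=float)
    if np.abs(P.sum(axis=1) - 1).max() > 1e-9:
        raise ValueError("P must be row-stochastic")
    rng = np.random.default_rng(seed)
    T = int(round(duration / dt))
    path = np.zeros(T, dtype=int)
    path[0] = rng.choice(N, p=pi) if pi is not None else rng.integers(N)
    for t in range(1, T):
        path[t] = rng.choice(N, p=P[path[t - 1]])
    units = []
    for j in range(M):
        times = []
        lam = Lambda[path, j] * dt
        counts = rng.poisson(lam)
        for t in np.flatnonzero(counts):
            times.append(t * dt + rng.uniform(0, dt, counts[t]))
        st = np.sort(np.concatenate(times)) if times else np.array([])
        if len(st) > 1:
            ok = np.concatenate([[True], np.diff(st) >= REFRACTORY_FLOOR])
            st = st[ok]
        units.append({"unit_id": j, "electrode_id": j, "spike_times": st})
    return SpikeTrainSet(units=units, duration=duration), path


# ---------------------------------------------------------------------------
# Planted precise spike patterns


@dataclass
class PlantSpec:
    """A planted precise pair: n1-spike then n2-spike at a fixed interval
    in a window around each occurrence of a drawing component."""

    n1: int
    n2: int
    delta: float                       # s between the pair's spikes
    window: tuple[float, float] = (-0.4, -0.1)   # s relative to occurrences
    jitter_sd: float = 0.0
    participation: float = 1.0


def embed_precise_patterns(spikes: SpikeTrainSet, occurrences: np.ndarray,
                           plants: list[PlantSpec], seed: int = 0
                           ) -> tuple[SpikeTrainSet, dict]:
    """Insert precise spike pairs around component occurrences.

    For each occurrence (with the plant's participation probability) an
    n1 spike is placed uniformly in the window and an n2 spike follows
    at delta + Gaussian jitter.  Insertions violating the refractory
    floor are skipped and logged.  Returns (new trains, ledger).
    """
    rng = np.random.default_rng(seed)
    new_times = [list(spikes.spike_times(i)) for i in range(spikes.n_units)]
    ledger = []
    skipped = 0
    for plant in plants:
        if spikes.electrode(plant.n1) == spikes.electrode(plant.n2):
            raise ValueError("planted pair must be on different electrodes")
        for T0 in np.asarray(occurrences, dtype=float):
            if rng.uniform() > plant.participation:
                continue
            lo, hi = T0 + plant.window[0], T0 + plant.window[1]
            t1 = rng.uniform(lo, max(lo, hi - plant.delta - 3 * plant.jitter_sd))
            t2 = t1 + plant.delta + (rng.normal(0, plant.jitter_sd) if plant.jitter_sd > 0 else 0.0)
            if not (0 <= t1 <= spikes.duration and 0 <= t2 <= spikes.duration):
                skipped += 1
                continue
            ok = True
            for n, tt in ((plant.n1, t1), (plant.n2, t2)):
                arr = new_times[n]
                if arr and min(abs(a - tt) for a in arr) < REFRACTORY_FLOOR:
                    ok = False
            if not ok:
                skipped += 1
                continue
            new_times[plant.n1].append(t1)
            new_times[plant.n2].append(t2)
            ledger.append({"n1": plant.n1, "n2": plant.n2, "t1": t1, "t2": t2,
                           "occurrence": T0})
    units = [{"unit_id": spikes.units[i]["unit_id"],
              "electrode_id": spikes.units[i]["electrode_id"],
              "spike_times": np.sort(np.asarray(new_times[i]))}
             for i in range(spikes.n_units)]
    out = SpikeTrainSet(units=units, duration=spikes.duration)
    return out, {"insertions": ledger, "skipped": skipped, "seed": seed}


def gen_poisson_trains(n_units: int, rate: float, duration: float, seed: int = 0,
                       electrodes: list | None = None) -> SpikeTrainSet:
    """Homogeneous Poisson trains (refractory floor enforced by deletion)."""
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_units):
        n = rng.poisson(rate * duration)
        st = np.sort(rng.uniform(0, duration, n))
        if len(st) > 1:
            ok = np.concatenate([[True], np.diff(st) >= REFRACTORY_FLOOR])
            st = st[ok]
        units.append({"unit_id": i,
                      "electrode_id": electrodes[i] if electrodes else i,
                      "spike_times": st})
    return SpikeTrainSet(units=units, duration=duration)


# ---------------------------------------------------------------------------
# Strokelet-grammar trajectories


def gen_syntax_trajectory(word_directions: list[float] | None = None,
                          n_strokes: int = 400, stroke_len: float = 60.0,
                          stroke_dur: float = 0.5, dwell: float = 0.9,
                          angle_noise_deg: float = 5.0, sample_rate: float = 100.0,
                          seed: int = 0) -> tuple[Trajectory, dict]:
    """To-and-fro scanning built from a cyclic word grammar.

    Each word is a scanning direction (degrees); within a word the pen
    strokes back and forth along that direction with a sinusoidal speed
    bump per stroke (accelerating then decelerating halves).  The word
    switches with probability ``1 - dwell`` after each stroke, cycling
    to the next word.  Truth labels give the word and the
    accelerating/decelerating half of every sample.
    """
    if word_directions is None:
        word_directions = [0.0, 90.0, 45.0]
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    n_per = int(round(stroke_dur / dt))
    tt = np.arange(n_per) / n_per
    # Sinusoidal speed bump integrates to a smooth displacement ramp.
    disp = 0.5 * (1 - np.cos(np.pi * tt))   # 0 -> ... -> ~1
    word = 0
    sense = 1.0
    pos = np.array([0.0, 0.0])
    xs, ys, wlab, alab = [], [], [], []
    for k in range(n_strokes):
        ang = np.radians(word_directions[word] + rng.normal(0, angle_noise_deg))
        d = np.array([np.cos(ang), np.sin(ang)]) * sense
        seg = pos[None, :] + stroke_len * disp[:, None] * d[None, :]
        xs.append(seg[:, 0])
        ys.append(seg[:, 1])
        wlab.append(np.full(n_per, word))
        # First half of the bump accelerates, second half decelerates.
        acc = np.zeros(n_per, dtype=int)
        acc[:n_per // 2] = 1
        alab.append(acc)
        pos = seg[-1]
        sense = -sense
        if rng.uniform() > dwell:
            word = (word + 1) % len(word_directions)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.arange(len(x)) * dt
    truth = {"word": np.concatenate(wlab), "accel": np.concatenate(alab),
             "n_words": len(word_directions), "seed": seed,
             "stroke_samples": n_per}
    return Trajectory(t, x, y), truth
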