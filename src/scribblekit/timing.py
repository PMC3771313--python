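"""Spike-timing precision analysis.

Tests whether spike times carry information at millisecond precision by
relating *drawing components* (recurring events in the movement, such as a
transition of the movement direction from one 30-degree sector to another)
to *neural components* (ordered pairs of units on different electrodes
firing with a particular delay).  The *support* of such a relation is the
number of ordered spike pairs whose latency falls in the most frequent of
50 narrow interval bins, pooled over time windows anchored to the drawing
events.  Significance is assessed with *teetering* surrogates in which
every spike is displaced uniformly within ``±W/2``: an inner teetered
ensemble normalizes each relation's support into a *surprise* (bits), the
summed surprise of the strongest relations gives a *relations-score*, and
an outer surrogate loop turns the score into a p-value.  Scanning the
teetering window ``W`` downward locates the temporal precision at which
the structure lives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .kinematics import Trajectory, differentiate
from .spikehmm import SpikeTrainSet

__all__ = [
    "DrawingComponent",
    "NeuralComponent",
    "Relation",
    "RelationsScoreResult",
    "INTERVAL_BINS_WIDE",
    "INTERVAL_BINS_NARROW",
    "WINDOW_PRESET_COARSE",
    "WINDOW_PRESET_FINE",
    "extract_drawing_components",
    "enumerate_components",
    "valid_pairs",
    "count_support",
    "teeter",
    "normal_tail_probability",
    "relation_surprise",
    "relations_score",
    "significance_scan",
]

N_INTERVAL_BINS = 50

# Interval-bin set 1: fifty 1 ms bins covering odd milliseconds of the
# 0-99 ms latency range (0-1, 2-3, ..., 98-99 ms).
INTERVAL_BINS_WIDE = np.column_stack([
    np.arange(N_INTERVAL_BINS) * 0.002,
    np.arange(N_INTERVAL_BINS) * 0.002 + 0.001,
])

# Interval-bin set 2: fifty 0.9 ms bins at 1 ms stride over 0-50 ms
# (0-0.9, 1-1.9, ..., 49-49.9 ms).
INTERVAL_BINS_NARROW = np.column_stack([
    np.arange(N_INTERVAL_BINS) * 0.001,
    np.arange(N_INTERVAL_BINS) * 0.001 + 0.0009,
])

# Candidate anchoring windows (seconds relative to a drawing event).
# Coarse: 0.3 s wide, stepping 0.2 s, from [-1.4, -1.1] to [-0.2, 0.1].
WINDOW_PRESET_COARSE = [(-1.4 + 0.2 * k, -1.1 + 0.2 * k) for k in range(7)]
# Fine: 0.1 s wide, from [-1.0, -0.9] to [-0.1, 0.0].
WINDOW_PRESET_FINE = [(-1.0 + 0.1 * k, -0.9 + 0.1 * k) for k in range(10)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DrawingComponent:
    """A recurring drawing event: a property transition or a frequent
    subsequence of such transitions, with the times at which it occurred."""

    name: str
    kind: str                      # "direction" | "speed" | "sequence"
    occurrences: np.ndarray        # sorted event times, s

    def __post_init__(self):
        occ = np.asarray(self.occurrences, dtype=float)
        if occ.size > 1 and np.any(np.diff(occ) < 0):
            occ = np.sort(occ)
        self.occurrences = occ

    @property
    def support(self) -> int:
        return int(self.occurrences.size)


@dataclass(frozen=True)
class NeuralComponent:
    """An ordered pair of units on different electrodes together with a
    latency bin index (``delta_bin`` among the 50 interval bins)."""

    n1: int
    n2: int
    delta_bin: int


@dataclass
class Relation:
    """A (drawing component, neural pair) relation with its support."""

    component: DrawingComponent
    n1: int
    n2: int
    window: tuple[float, float]
    counts: np.ndarray             # per-interval-bin pooled pair counts
    best_bin: int
    support: int
    surprise: float | None = None  # bits; None until computed / if sigma=0
    n_skipped: int = 0             # occurrences whose window left the record


@dataclass
class RelationsScoreResult:
    """Relations-score of a record with its outer-surrogate calibration."""

    s0: float                      # bits
    w: float                       # teetering window used for normalization, s
    noise_threshold: int
    relations: list[Relation] = field(default_factory=list)
    surrogate_scores: np.ndarray | None = None
    p_value: float | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Drawing components
# ---------------------------------------------------------------------------

def extract_drawing_components(
    traj: Trajectory,
    direction_bin_deg: float = 30.0,
    speed_bin: float = 100.0,
    min_speed: float = 10.0,
    min_support: int = 10,
    max_len: int = 3,
) -> list[DrawingComponent]:
    """Quantize movement direction and speed, emit an event at every
    transition between quantization levels, and return the frequent single
    events and event subsequences as drawing components.

    Parameters
    ----------
    direction_bin_deg : width of the direction sectors (degrees).
    speed_bin : width of the speed levels (mm/s).
    min_speed : below this speed (mm/s) direction is undefined and no
        direction events are emitted.
    min_support : minimum number of occurrences for a component.
    max_len : longest event subsequence mined.
    """
    prof = differentiate(traj)
    t = traj.t
    ok = prof.defined & (prof.speed > min_speed)

    events: list[tuple[float, str]] = []

    direction = np.degrees(np.arctan2(prof.vy, prof.vx)) % 360.0
    dir_level = np.floor(direction / direction_bin_deg).astype(int)
    speed_level = np.floor(prof.speed / speed_bin).astype(int)

    for levels, kind, gate in ((dir_level, "dir", ok), (speed_level, "spd", prof.defined)):
        valid = np.flatnonzero(gate[:-1] & gate[1:] & (levels[:-1] != levels[1:]))
        for i in valid:
            events.append((0.5 * (t[i] + t[i + 1]),
                           f"{kind}:{levels[i]}->{levels[i + 1]}"))

    events.sort()
    if not events:
        warnings.warn("no quantized-property transitions found")
        return []

    times = np.array([e[0] for e in events])
    symbols = [e[1] for e in events]

    components: list[DrawingComponent] = []
    for length in range(1, max_len + 1):
        seqs: dict[tuple, list[float]] = {}
        for i in range(len(symbols) - length + 1):
            key = tuple(symbols[i:i + length])
            # the component occurs when its last event completes
            seqs.setdefault(key, []).append(times[i + length - 1])
        for key, occ in seqs.items():
            if len(occ) >= min_support:
                kind = "sequence" if length > 1 else (
                    "direction" if key[0].startswith("dir") else "speed")
                components.append(DrawingComponent(
                    name=" ".join(key), kind=kind,
                    occurrences=np.asarray(occ)))
    if not components:
        warnings.warn(f"no components with support >= {min_support}")
    return components


# ---------------------------------------------------------------------------
# Combinatorics
# ---------------------------------------------------------------------------

def valid_pairs(data: SpikeTrainSet) -> list[tuple[int, int]]:
    """All ordered unit pairs recorded on different electrodes."""
    n = data.n_units
    return [(i, j) for i in range(n) for j in range(n)
            if i != j and data.electrode(i) != data.electrode(j)]


def enumerate_components(
    n_electrodes: int,
    units_per_electrode: int,
    n_intervals: int = N_INTERVAL_BINS,
    n_drawing_components: int = 1,
) -> dict:
    """Exact counts of ordered cross-electrode pairs and their products
    with interval bins and drawing components.

    ``valid_pairs`` is the number of pair-component combinations — it
    equals the raw ordered cross-electrode pair count when only one
    drawing component is considered.
    """
    if min(n_electrodes, units_per_electrode, n_intervals,
           n_drawing_components) < 1:
        raise ValueError("all counts must be >= 1")
    n_units = n_electrodes * units_per_electrode
    ordered = n_units * (n_units - 1)
    same_electrode = n_electrodes * units_per_electrode * (units_per_electrode - 1)
    pairs = ordered - same_electrode
    return {
        "valid_pairs": pairs * n_drawing_components,
        "potential_neural_components": pairs * n_intervals,
        "pair_component_interval_triples":
            pairs * n_intervals * n_drawing_components,
    }


# ---------------------------------------------------------------------------
# Support counting
# ---------------------------------------------------------------------------

def _bin_edges(bins: np.ndarray) -> tuple[np.ndarray, float]:
    """Interleave (lo, hi) bin bounds into a flat edge array for
    searchsorted-based binning; also return the largest latency covered."""
    edges = np.ravel(bins)
    if np.any(np.diff(edges) < 0):
        raise ValueError("interval bins must be sorted and non-overlapping")
    return edges, float(bins[-1, 1])


def _candidate_pairs(
    t1: np.ndarray,
    t2: np.ndarray,
    occurrences: np.ndarray,
    window: tuple[float, float],
    duration: float,
    max_lat: float,
    margin: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Indices (into t1, t2) of all ordered spike pairs whose first spike
    lies in an occurrence window and whose latency is within
    ``[-margin, max_lat + margin]``.  Returns (idx1, idx2, n_skipped)."""
    t_from, t_to = window
    starts = occurrences + t_from
    stops = occurrences + t_to
    inside = (starts >= 0) & (stops <= duration)
    n_skipped = int(np.sum(~inside))
    starts, stops = starts[inside], stops[inside]

    lo1 = np.searchsorted(t1, starts, side="left")
    hi1 = np.searchsorted(t1, stops, side="right")
    n_in = hi1 - lo1
    if n_in.sum() == 0:
        return (np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp),
                n_skipped)
    idx1 = np.concatenate([np.arange(a, b) for a, b in zip(lo1, hi1) if b > a])

    s1 = t1[idx1]
    lo2 = np.searchsorted(t2, s1 - margin, side="left")
    hi2 = np.searchsorted(t2, s1 + max_lat + margin, side="right")
    n2 = hi2 - lo2
    keep = n2 > 0
    if not np.any(keep):
        return (np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp),
                n_skipped)
    rep1 = np.repeat(idx1[keep], n2[keep])
    rep2 = np.concatenate([np.arange(a, b)
                           for a, b in zip(lo2[keep], hi2[keep])])
    return rep1, rep2, n_skipped


def _support_from_latencies(lat: np.ndarray, edges: np.ndarray,
                            n_rows: int = 1) -> np.ndarray:
    """Histogram latencies into the 50 interval bins.  ``lat`` may be 1-D
    (one record) or 2-D ``(n_rows, n_pairs)`` (a surrogate ensemble);
    returns counts of shape ``(n_rows, 50)``."""
    flat = np.ravel(lat)
    pos = np.searchsorted(edges, flat, side="right")
    in_bin = (pos % 2) == 1
    bin_idx = (pos - 1) // 2
    if lat.ndim == 2:
        rows = np.repeat(np.arange(lat.shape[0]), lat.shape[1])
        key = rows[in_bin] * N_INTERVAL_BINS + bin_idx[in_bin]
        return np.bincount(
            key, minlength=lat.shape[0] * N_INTERVAL_BINS
        ).reshape(lat.shape[0], N_INTERVAL_BINS)
    return np.bincount(
        bin_idx[in_bin], minlength=N_INTERVAL_BINS
    )[None, :]


def count_support(
    data: SpikeTrainSet,
    pair: tuple[int, int],
    component: DrawingComponent,
    window: tuple[float, float],
    bins: np.ndarray = INTERVAL_BINS_WIDE,
) -> Relation:
    """Count, for one ordered unit pair and one drawing component, how many
    times a spike of the first unit inside an occurrence window was followed
    by a spike of the second unit at a latency falling in each of the 50
    interval bins.  The relation's support is the count of the fullest bin.
    """
    if component.support < 1:
        raise ValueError("component has no occurrences")
    n1, n2 = pair
    if data.electrode(n1) == data.electrode(n2):
        raise ValueError("pair must span two electrodes")
    edges, max_lat = _bin_edges(bins)
    idx1, idx2, n_skipped = _candidate_pairs(
        data.spike_times(n1), data.spike_times(n2),
        component.occurrences, window, data.duration, max_lat)
    lat = data.spike_times(n2)[idx2] - data.spike_times(n1)[idx1]
    counts = _support_from_latencies(lat, edges)[0]
    best = int(np.argmax(counts))
    return Relation(component=component, n1=n1, n2=n2, window=window,
                    counts=counts, best_bin=best,
                    support=int(counts[best]), n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Teetering surrogates
# ---------------------------------------------------------------------------

def _teeter_rows(
    t: np.ndarray,
    w: float,
    refractory: float,
    rng: np.random.Generator,
    n_rows: int,
    max_rounds: int = 100,
    unit_label: object = "?",
) -> np.ndarray:
    """``n_rows`` independent teeters of one spike train, vectorized.

    Each spike is redrawn uniformly in ``±w/2`` of its true time; spikes of
    the same unit that land closer than the refractory period are redrawn
    (both members of the offending gap), with a bounded number of rounds.
    """
    if t.size == 0:
        return np.zeros((n_rows, 0))
    out = t[None, :] + rng.uniform(-w / 2, w / 2, (n_rows, t.size))
    if t.size == 1 or refractory <= 0:
        return out
    if np.any(np.diff(t) < refractory):
        raise ValueError(f"unit {unit_label}: data violate the refractory period")
    for _ in range(max_rounds):
        gaps = np.diff(out, axis=1)
        bad = gaps < refractory
        if not np.any(bad):
            return out
        redraw = np.zeros_like(out, dtype=bool)
        redraw[:, :-1] |= bad
        redraw[:, 1:] |= bad
        out[redraw] = (t[None, :] + rng.uniform(
            -w / 2, w / 2, out.shape))[redraw]
    raise ValueError(
        f"unit {unit_label}: could not resolve refractory conflicts while "
        f"teetering (window {w * 1e3:g} ms)")


def teeter(
    data: SpikeTrainSet,
    w: float,
    refractory: float = 0.001,
    seed: int | np.random.Generator = 0,
) -> SpikeTrainSet:
    """Teetered surrogate of a whole record: every spike of every unit is
    replaced by a random time within ``±w/2`` of its true time, preserving
    spike counts and the refractory period."""
    if w <= 0:
        raise ValueError("teetering window must be positive")
    rng = np.random.default_rng(seed)
    units = []
    for u in data.units:
        st = _teeter_rows(u["spike_times"], w, refractory, rng, 1,
                          unit_label=u["unit_id"])[0]
        st = np.sort(np.clip(st, 0.0, data.duration))
        units.append({**u, "spike_times": st})
    return SpikeTrainSet(units=units, duration=data.duration)


def normal_tail_probability(support: float, mu: float, sd: float) -> float:
    """One-sided upper-tail probability of an observed support under a
    normal fit (mean ``mu``, SD ``sd``) to the teetered ensemble."""
    if sd <= 0:
        raise ValueError("ensemble SD must be positive")
    return float(norm.sf((support - mu) / sd))


def relation_surprise(
    relation: Relation,
    data: SpikeTrainSet,
    w: float,
    n_inner: int = 1000,
    refractory: float = 0.001,
    bins: np.ndarray = INTERVAL_BINS_WIDE,
    seed: int | np.random.Generator = 0,
    empirical_tail: bool = False,
) -> float | None:
    """Surprise of a relation, in bits.

    An ensemble of ``n_inner`` teetered surrogates of the two involved
    trains yields a null distribution of supports; the observed support is
    converted to an upper-tail probability under a normal fit (mean and SD
    of the ensemble) and the surprise is ``-log2`` of that probability.
    Returns ``None`` (and flags the relation) when the ensemble SD is zero.
    With ``empirical_tail=True`` the ensemble's own upper-tail fraction is
    used instead of the normal approximation.
    """
    rng = np.random.default_rng(seed)
    edges, max_lat = _bin_edges(bins)
    t1 = data.spike_times(relation.n1)
    t2 = data.spike_times(relation.n2)
    idx1, idx2, _ = _candidate_pairs(
        t1, t2, relation.component.occurrences, relation.window,
        data.duration, max_lat, margin=w)
    if idx1.size == 0:
        relation.surprise = None
        return None
    u1 = np.unique(idx1)
    u2 = np.unique(idx2)
    r1 = _teeter_rows(t1[u1], w, refractory, rng, n_inner,
                      unit_label=relation.n1)
    r2 = _teeter_rows(t2[u2], w, refractory, rng, n_inner,
                      unit_label=relation.n2)
    # map global spike indices into the unique-subset columns
    c1 = np.searchsorted(u1, idx1)
    c2 = np.searchsorted(u2, idx2)
    lat = r2[:, c2] - r1[:, c1]
    supports = _support_from_latencies(lat, edges, n_rows=n_inner).max(axis=1)
    mu = float(np.mean(supports))
    sd = float(np.std(supports))
    if sd == 0.0:
        relation.surprise = None
        return None
    if empirical_tail:
        p = float(np.mean(supports >= relation.support))
        p = max(p, 1.0 / (n_inner + 1))
    else:
        p = max(normal_tail_probability(relation.support, mu, sd),
                np.finfo(float).tiny)
    relation.surprise = float(-np.log2(p))
    return relation.surprise


# ---------------------------------------------------------------------------
# Relations-score and the precision scan
# ---------------------------------------------------------------------------

def _dedup_and_sum(relations: list[Relation], n_top: int = 10
                   ) -> tuple[float, list[Relation], list[str]]:
    """Sort by descending surprise, drop later relations that repeat the
    same (pair, interval), let each pair contribute only once, and sum the
    surprises of the first ``n_top`` survivors."""
    flags: list[str] = []
    scored = [r for r in relations if r.surprise is not None]
    scored.sort(key=lambda r: r.surprise, reverse=True)
    seen_triple: set[tuple] = set()
    seen_pair: set[tuple] = set()
    kept: list[Relation] = []
    for r in scored:
        triple = (r.n1, r.n2, r.best_bin)
        pair = (r.n1, r.n2)
        if triple in seen_triple or pair in seen_pair:
            continue
        seen_triple.add(triple)
        seen_pair.add(pair)
        kept.append(r)
    if not kept:
        flags.append("no surviving relations")
        return 0.0, [], flags
    if len(kept) < n_top:
        flags.append(f"only {len(kept)} surviving relations (< {n_top})")
    top = kept[:n_top]
    return float(sum(r.surprise for r in top)), top, flags


def relations_score(
    data: SpikeTrainSet,
    components: list[DrawingComponent],
    w: float,
    windows: list[tuple[float, float]] | tuple[float, float] = None,
    bins: np.ndarray = INTERVAL_BINS_WIDE,
    noise_threshold: int = 20,
    n_inner: int = 1000,
    n_top: int = 10,
    refractory: float = 0.001,
    seed: int | np.random.Generator = 0,
    empirical_tail: bool = False,
) -> RelationsScoreResult:
    """Relations-score ``S0`` of a record at teetering window ``w``.

    Every ordered cross-electrode pair is combined with every drawing
    component; relations whose support falls below ``noise_threshold`` are
    pruned, the rest are normalized into surprises by inner teetered
    ensembles, duplicates are removed, and the ``n_top`` largest surprises
    are summed.  When several candidate ``windows`` are given, the window
    with the largest score is selected.
    """
    rng = np.random.default_rng(seed)
    if windows is None:
        windows = [(-0.4, -0.1)]
    elif isinstance(windows, tuple):
        windows = [windows]

    best: RelationsScoreResult | None = None
    for window in windows:
        relations: list[Relation] = []
        for pair in valid_pairs(data):
            for comp in components:
                rel = count_support(data, pair, comp, window, bins=bins)
                if rel.support >= noise_threshold:
                    relations.append(rel)
        for rel in relations:
            relation_surprise(rel, data, w, n_inner=n_inner,
                              refractory=refractory, bins=bins,
                              seed=rng, empirical_tail=empirical_tail)
        s0, top, flags = _dedup_and_sum(relations, n_top=n_top)
        res = RelationsScoreResult(s0=s0, w=w,
                                   noise_threshold=noise_threshold,
                                   relations=top, flags=flags)
        if best is None or res.s0 > best.s0:
            best = res
            best.flags = list(flags) + (
                [f"window {window} selected"] if len(windows) > 1 else [])
    return best


def significance_scan(
    data: SpikeTrainSet,
    components: list[DrawingComponent],
    w_list: list[float],
    n_outer: int = 200,
    alpha: float = 0.01,
    windows: list[tuple[float, float]] | tuple[float, float] = None,
    bins: np.ndarray = INTERVAL_BINS_WIDE,
    noise_threshold: int = 20,
    n_inner: int = 1000,
    n_top: int = 10,
    refractory: float = 0.001,
    seed: int = 0,
) -> dict:
    """Scan teetering windows for the smallest one at which the record's
    relations-score is significant.

    For each ``w`` the score of the real record is compared against
    ``n_outer`` surrogates in which the whole record is teetered at ``w``
    and the entire score computation — support counting, pruning, inner
    normalization, best-window and best-interval selection — is redone.
    ``p`` is the fraction of surrogate scores at least as large as the real
    score.  Returns per-``w`` results and the smallest significant ``w``.
    """
    rng = np.random.default_rng(seed)
    results = []
    for w in sorted(w_list, reverse=True):
        real = relations_score(
            data, components, w, windows=windows, bins=bins,
            noise_threshold=noise_threshold, n_inner=n_inner, n_top=n_top,
            refractory=refractory, seed=rng)
        surr = np.empty(n_outer)
        for k in range(n_outer):
            shuffled = teeter(data, w, refractory=refractory, seed=rng)
            surr[k] = relations_score(
                shuffled, components, w, windows=windows, bins=bins,
                noise_threshold=noise_threshold, n_inner=n_inner,
                n_top=n_top, refractory=refractory, seed=rng).s0
        p = float(np.mean(surr >= real.s0))
        real.surrogate_scores = surr
        real.p_value = p
        results.append({"w": w, "s0": real.s0, "p_value": p,
                        "significant": p < alpha, "result": real})
    sig = [r["w"] for r in results if r["significant"]]
    return {
        "per_w": results,
        "alpha": alpha,
        "min_significant_w": min(sig) if sig else None,
    }
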