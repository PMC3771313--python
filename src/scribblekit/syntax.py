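"""Strokelet syntax analysis.

Decomposes a scribble into *strokelets* — spans between adjacent extrema
of the tangential speed, so accelerating and decelerating strokelets
strictly alternate — describes each by ten tangent angles along its arc
plus the acceleration flag, groups the descriptors with Gaussian mixture
models (separately for the two acceleration classes), and studies the
grammar of the movement through the matrix of transition probabilities
between groups.  Agglomerative information-bottleneck clustering
compresses the groups while preserving the mutual information between a
strokelet and its successor; cycles in the thresholded cluster-level
transition graph are the "words" of the scribble and the transitions
between cycles its "sentence" structure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

from .kinematics import Trajectory, differentiate

__all__ = [
    "Strokelet",
    "StrokeletDescriptor",
    "TransitionModel",
    "parse_strokelets",
    "describe",
    "group_strokelets",
    "transition_model",
    "ib_cluster",
    "information_retention",
    "extract_cycles",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class Strokelet:
    """A span of the trajectory between adjacent tangential-speed extrema."""

    traj: Trajectory
    start: int                  # sample indices into the parent trajectory
    stop: int                   # exclusive
    accel: bool                 # speed increasing over the span

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class StrokeletDescriptor:
    """Ten tangent angles at equally spaced arc-length points + accel."""

    angles: np.ndarray          # (10,), radians, unwrapped within strokelet
    accel: bool

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.shape != (10,):
            raise ValueError("descriptor must have exactly 10 angles")
        self.angles = a


@dataclass
class TransitionModel:
    """First-order transition structure between strokelet groups."""

    labels: np.ndarray          # group label per strokelet, in time order
    counts: np.ndarray          # (G, G) transition counts
    conditional: np.ndarray     # rows normalized where row count > 0
    ib_clusters: np.ndarray | None = None   # cluster id per group (-1: dropped)
    cluster_matrix: np.ndarray | None = None
    retention: float | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Parsing and description
# ---------------------------------------------------------------------------

def parse_strokelets(
    traj: Trajectory,
    epoch: tuple[float, float] | None = None,
    prominence_frac: float = 0.05,
    smooth_window: int = 11,
) -> list[Strokelet]:
    """Cut the trajectory at local extrema of the tangential speed.

    Extrema are prominence-filtered (default 5% of the epoch's speed
    range); consecutive extrema of the same kind are merged, so the accel
    flags of the returned strokelets strictly alternate.  A monotone
    speed profile yields a single strokelet.
    """
    prof = differentiate(traj, smooth_window=smooth_window)
    i0, i1 = 0, traj.t.size
    if epoch is not None:
        i0 = int(np.searchsorted(traj.t, epoch[0], side="left"))
        i1 = int(np.searchsorted(traj.t, epoch[1], side="right"))
    speed = prof.speed[i0:i1]
    if speed.size < 3:
        raise ValueError("epoch too short")
    prom = prominence_frac * max(np.ptp(speed), 1e-12)
    maxima, _ = find_peaks(speed, prominence=prom)
    minima, _ = find_peaks(-speed, prominence=prom)
    ext = sorted([(int(i), +1) for i in maxima] + [(int(i), -1) for i in minima])

    # enforce alternation: among consecutive extrema of one kind keep the
    # most extreme
    cleaned: list[tuple[int, int]] = []
    for i, kind in ext:
        if cleaned and cleaned[-1][1] == kind:
            j, _ = cleaned[-1]
            better = i if kind * speed[i] > kind * speed[j] else j
            cleaned[-1] = (better, kind)
        else:
            cleaned.append((i, kind))

    bounds = [0] + [i for i, _ in cleaned if 0 < i < speed.size - 1] \
        + [speed.size - 1]
    bounds = sorted(set(bounds))
    strokelets = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 1:
            continue
        strokelets.append(Strokelet(
            traj=traj, start=i0 + a, stop=i0 + b + 1,
            accel=bool(speed[b] > speed[a])))
    if len(strokelets) == 1:
        warnings.warn("monotone speed profile: single strokelet")
    return strokelets


def describe(strokelet: Strokelet) -> StrokeletDescriptor:
    """Tangent angle at 10 equally spaced arc-length points, unwrapped."""
    tr = strokelet.traj
    x = tr.x[strokelet.start:strokelet.stop]
    y = tr.y[strokelet.start:strokelet.stop]
    if x.size < 2:
        raise ValueError("zero-length strokelet")
    dx = np.diff(x)
    dy = np.diff(y)
    seg = np.hypot(dx, dy)
    if seg.sum() <= 0:
        raise ValueError("degenerate strokelet (no displacement)")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # tangent angle of each segment, assigned to its midpoint arc length
    ang = np.unwrap(np.arctan2(dy, dx))
    mid = 0.5 * (s[:-1] + s[1:])
    targets = np.linspace(0.0, s[-1], 10)
    angles = np.interp(targets, mid, ang)
    return StrokeletDescriptor(angles=angles, accel=strokelet.accel)


# ---------------------------------------------------------------------------
# GMM grouping
# ---------------------------------------------------------------------------

def group_strokelets(
    descriptors: list[StrokeletDescriptor],
    k_range: tuple[int, int] = (15, 25),
    seed: int = 0,
    holdout: float = 0.25,
) -> np.ndarray:
    """Group descriptors with Gaussian mixtures, separately for the
    accelerating and decelerating classes.

    Angles are embedded as (cos, sin) pairs; within each class the
    component count is chosen from ``k_range`` by held-out
    log-likelihood.  Returns one global integer label per descriptor
    (labels of the two classes do not overlap).
    """
    accel_flags = np.array([d.accel for d in descriptors])
    feats = np.array([
        np.concatenate([np.cos(d.angles), np.sin(d.angles)])
        for d in descriptors])
    labels = np.full(len(descriptors), -1, dtype=int)
    rng = np.random.default_rng(seed)
    offset = 0
    for cls in (True, False):
        idx = np.flatnonzero(accel_flags == cls)
        if idx.size < 50:
            raise ValueError(
                f"need at least 50 strokelets per class, got {idx.size}")
        x = feats[idx]
        perm = rng.permutation(idx.size)
        n_hold = max(1, int(holdout * idx.size))
        hold, train = perm[:n_hold], perm[n_hold:]
        best_k, best_ll = None, -np.inf
        for k in range(k_range[0], k_range[1] + 1):
            if k > train.size:
                break
            gm = GaussianMixture(
                n_components=k, covariance_type="diag", reg_covar=1e-4,
                random_state=int(rng.integers(2 ** 31)), n_init=1)
            gm.fit(x[train])
            ll = gm.score(x[hold])
            if ll > best_ll:
                best_ll, best_k = ll, k
        gm = GaussianMixture(
            n_components=best_k, covariance_type="diag", reg_covar=1e-4,
            random_state=int(rng.integers(2 ** 31)), n_init=2)
        labels[idx] = offset + gm.fit_predict(x)
        offset += best_k
    return labels


def transition_model(labels: np.ndarray,
                     n_groups: int | None = None) -> TransitionModel:
    """First-order transition counts and conditional probabilities."""
    labels = np.asarray(labels, dtype=int)
    g = int(labels.max()) + 1 if n_groups is None else n_groups
    counts = np.zeros((g, g))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    rows = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(rows > 0, counts / np.maximum(rows, 1), 0.0)
    return TransitionModel(labels=labels, counts=counts, conditional=cond)


# ---------------------------------------------------------------------------
# Agglomerative information bottleneck
# ---------------------------------------------------------------------------

def _mutual_information(joint: np.ndarray) -> float:
    """I(X;Y) in bits of a joint probability table."""
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(joint > 0, joint / (px * py), 1.0)
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    return float(terms.sum())


def _merge_cost(pa: float, pb: float, qa: np.ndarray, qb: np.ndarray) -> float:
    """Information loss of merging two clusters (weighted JS divergence)."""
    w = pa + pb
    m = (pa * qa + pb * qb) / w

    def h(q):
        nz = q > 0
        return -float(np.sum(q[nz] * np.log2(q[nz])))

    return w * h(m) - pa * h(qa) - pb * h(qb)


def ib_cluster(transitions: TransitionModel | np.ndarray,
               n_clusters: int = 12) -> TransitionModel:
    """Agglomerative information-bottleneck clustering of the groups.

    The current group is X and the next group is Y; groups are merged
    greedily, always taking the pair whose merge loses the least mutual
    information I(T; Y) (ties broken by lexicographic group index), until
    ``n_clusters`` clusters remain.  Groups with no outgoing transitions
    are excluded (label -1).  The returned model carries the cluster
    assignment, the cluster-level conditional matrix, and the information
    retention I(T;Y) / I(X;Y).
    """
    if isinstance(transitions, TransitionModel):
        model = transitions
    else:
        counts = np.asarray(transitions, dtype=float)
        model = TransitionModel(labels=np.empty(0, dtype=int), counts=counts,
                                conditional=np.zeros_like(counts))
    counts = model.counts
    g = counts.shape[0]
    active = np.flatnonzero(counts.sum(axis=1) > 0)
    if n_clusters > active.size:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds {active.size} usable groups")

    total = counts[active].sum()
    p = counts[active].sum(axis=1) / total        # p(x) over active groups
    q = counts[active] / counts[active].sum(axis=1, keepdims=True)  # p(y|x)

    clusters: list[list[int]] = [[i] for i in range(active.size)]
    pw = list(p)
    qw = [q[i] for i in range(active.size)]

    while len(clusters) > n_clusters:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            cost = _merge_cost(pw[a], pw[b], qw[a], qw[b])
            key = (cost, clusters[a][0], clusters[b][0])
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        w = pw[a] + pw[b]
        qw[a] = (pw[a] * qw[a] + pw[b] * qw[b]) / w
        pw[a] = w
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b], pw[b], qw[b]

    # canonical cluster order: by first (lowest) member
    order = np.argsort([c[0] for c in clusters])
    assign = np.full(g, -1, dtype=int)
    for new_id, ci in enumerate(order):
        for member in clusters[ci]:
            assign[active[member]] = new_id

    # cluster-level matrix over (cluster, next-cluster)
    k = len(clusters)
    joint_xy = counts[np.ix_(active, active)]
    joint_xy = counts[active][:, :]  # rows active, columns all groups
    cl_counts = np.zeros((k, k))
    for gi in active:
        for gj in range(g):
            if counts[gi, gj] > 0 and assign[gj] >= 0:
                cl_counts[assign[gi], assign[gj]] += counts[gi, gj]
    rows = cl_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cl_cond = np.where(rows > 0, cl_counts / np.maximum(rows, 1), 0.0)

    # retention I(T;Y)/I(X;Y) with Y = next group
    joint_full = counts[active] / total
    i_xy = _mutual_information(joint_full)
    joint_t = np.zeros((k, counts.shape[1]))
    for gi in active:
        joint_t[assign[gi]] += counts[gi] / total
    i_ty = _mutual_information(joint_t)
    flags = list(model.flags)
    if i_xy < 1e-9:
        retention = 1.0
        flags.append("no structure (I(X;Y) ~ 0)")
    else:
        retention = i_ty / i_xy
    return TransitionModel(labels=model.labels, counts=counts,
                           conditional=model.conditional,
                           ib_clusters=assign, cluster_matrix=cl_cond,
                           retention=float(retention), flags=flags)


def information_retention(model: TransitionModel) -> float:
    if model.retention is None:
        raise ValueError("run ib_cluster first")
    return model.retention


# ---------------------------------------------------------------------------
# Cycle ("word") extraction
# ---------------------------------------------------------------------------

def extract_cycles(cluster_matrix: np.ndarray,
                   threshold: float = 0.2) -> dict:
    """Words and sentence structure of the cluster-level transition graph.

    Edges with conditional probability >= ``threshold`` form a directed
    graph; its strongly connected components that contain a cycle are the
    words (reported in cycle order, starting from the lowest cluster id
    and following the most probable successor).  Above-threshold edges
    between different words are the gateway ("allophone") transitions.
    """
    m = np.asarray(cluster_matrix, dtype=float)
    k = m.shape[0]
    graph = nx.DiGraph()
    graph.add_nodes_from(range(k))
    for i in range(k):
        for j in range(k):
            if m[i, j] >= threshold:
                graph.add_edge(i, j, p=float(m[i, j]))

    words = []
    comp_of = {}
    for ci, comp in enumerate(nx.strongly_connected_components(graph)):
        comp = sorted(comp)
        sub = graph.subgraph(comp)
        has_cycle = len(comp) > 1 or graph.has_edge(comp[0], comp[0])
        for node in comp:
            comp_of[node] = (ci, has_cycle)
        if not has_cycle:
            continue
        # walk the cycle from the lowest member along the most probable
        # in-component successor
        order = [comp[0]]
        seen = {comp[0]}
        cur = comp[0]
        while True:
            succ = [(sub[cur][v]["p"], v) for v in sub.successors(cur)]
            if not succ:
                break
            _, nxt = max(succ)
            if nxt in seen:
                break
            order.append(nxt)
            seen.add(nxt)
            cur = nxt
        # include any members not on the main walk
        order += [c for c in comp if c not in seen]
        words.append(order)

    word_of = {}
    for wi, w in enumerate(words):
        for node in w:
            word_of[node] = wi
    gateways = []
    for i, j, d in graph.edges(data=True):
        wi, wj = word_of.get(i), word_of.get(j)
        if wi is not None and wj is not None and wi != wj:
            gateways.append({"from_cluster": i, "to_cluster": j,
                             "from_word": wi, "to_word": wj, "p": d["p"]})
    return {"words": words, "gateways": gateways,
            "n_words": len(words), "word_of_cluster": word_of}
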