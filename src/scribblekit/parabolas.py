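"""Parabolic movement primitives: segmentation, fitting, model choice, clustering.

Over-trained scribbling decomposes into strokes bounded by local minima
of Euclidean curvature, each containing one curvature maximum.  Each
stroke is fitted with a parabola in canonical form y = x**2 / (2p); the
focal parameter p equals the radius of curvature at the vertex, and the
orientation is the direction of the outward normal at the vertex.  Fit
quality is the unexplained-variance fraction

    D = 1 - R^2 = sum (y_i - x_i^2/2p)^2
                  / sum [ (x_i - mean x)^2 + (y_i - mean y)^2 ]

with residuals evaluated in the parabola's canonical frame.  Competing
shape models (ellipse, polynomials of order 3-5) are compared by the
Schwarz information criterion, and the fitted primitives are clustered
on (orientation, log p) to expose the small set of stroke classes that
emerges with practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .kinematics import KinematicProfile, Trajectory, differentiate, _runs_of_true

__all__ = [
    "Stroke",
    "ParabolicFit",
    "ParabolaClusterModel",
    "segment_activity",
    "segment_strokes_curvature",
    "fit_parabola",
    "model_selection_sic",
    "cluster_parabolas",
]


@dataclass(frozen=True)
class Stroke:
    """A contiguous sample span of a trajectory (inclusive indices)."""

    traj: Trajectory
    start_idx: int
    end_idx: int
    kind: str = "curvature-bounded"

    def __post_init__(self):
        if self.end_idx <= self.start_idx + 4:
            raise ValueError("stroke must span more than 5 samples")

    @property
    def x(self) -> np.ndarray:
        return self.traj.x[self.start_idx:self.end_idx + 1]

    @property
    def y(self) -> np.ndarray:
        return self.traj.y[self.start_idx:self.end_idx + 1]

    @property
    def t(self) -> np.ndarray:
        return self.traj.t[self.start_idx:self.end_idx + 1]

    def __len__(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass(frozen=True)
class ParabolicFit:
    p: float                 # focal parameter, mm
    orientation: float       # outward normal at the vertex, degrees in [0, 360)
    vertex: tuple[float, float]
    D: float                 # unexplained variance fraction
    euclidean_length: float


@dataclass
class ParabolaClusterModel:
    n_clusters: int
    assignments: np.ndarray          # -1 marks the outlier bin
    mean_orientation: np.ndarray     # degrees, circular mean per cluster
    mean_p: np.ndarray               # geometric mean focal parameter
    mean_vertex: np.ndarray          # (k, 2)
    circular_variance: np.ndarray    # 1 - mean resultant length per cluster
    p_log_variance: np.ndarray


def segment_activity(traj: Trajectory, v_rest: float = 10.0, min_dur: float = 0.25,
                     smooth_window: int = 11) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split a record into movement epochs and rest gaps.

    An epoch is a maximal run with speed >= ``v_rest`` (mm/s) lasting at
    least ``min_dur`` seconds.  Returns (epochs, rests) as inclusive
    sample-index pairs.
    """
    prof = differentiate(traj, smooth_window)
    moving = prof.speed >= v_rest
    min_len = max(1, int(round(min_dur / traj.dt)))
    epochs = [(a, b - 1) for a, b in _runs_of_true(moving) if b - a >= min_len]
    rest_mask = np.ones(len(traj), dtype=bool)
    for a, b in epochs:
        rest_mask[a:b + 1] = False
    rests = [(a, b - 1) for a, b in _runs_of_true(rest_mask)]
    return epochs, rests


def segment_strokes_curvature(traj: Trajectory, epoch: tuple[int, int] | None = None,
                              smooth_window: int = 11, min_prominence_frac: float = 0.10,
                              min_len: int = 8) -> list[Stroke]:
    """Cut an epoch into strokes at local minima of Euclidean curvature.

    Each stroke lies between consecutive curvature minima and contains a
    single interior curvature maximum.  Minima must exceed a prominence
    of ``min_prominence_frac`` times the epoch's curvature range.
    """
    i0, i1 = epoch if epoch is not None else (0, len(traj) - 1)
    prof = differentiate(traj, smooth_window)
    c = prof.curvature[i0:i1 + 1].copy()
    finite = np.isfinite(c)
    if finite.sum() < min_len:
        return []
    cmax, cmin = np.nanmax(c), np.nanmin(c)
    rng = cmax - cmin
    if rng <= 0:
        return [Stroke(traj, i0, i1)]
    prominence = min_prominence_frac * rng
    c_filled = np.where(finite, c, cmax)  # gaps act as high-curvature walls
    minima, _ = find_peaks(-c_filled, prominence=prominence)
    bounds = [0] + [int(m) for m in minima] + [len(c) - 1]
    strokes = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a + 1 >= min_len:
            strokes.append(Stroke(traj, i0 + a, i0 + b))
    return strokes


# ---------------------------------------------------------------------------
# Parabola fitting


def _quad_fit_in_frame(x: np.ndarray, y: np.ndarray, theta: float):
    """LS fit of y' = a x'^2 + b x' + c in the frame rotated by -theta.

    Returns (a, b, c, rss) or None when the design is singular.
    """
    ct, st = np.cos(theta), np.sin(theta)
    xr = ct * x + st * y
    yr = -st * x + ct * y
    A = np.column_stack([xr**2, xr, np.ones_like(xr)])
    coef, res, rank, _ = np.linalg.lstsq(A, yr, rcond=None)
    if rank < 3:
        return None
    rss = float(np.sum((A @ coef - yr) ** 2))
    return coef[0], coef[1], coef[2], rss, xr, yr


def _denominator(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2))


def fit_parabola(stroke: Stroke | tuple[np.ndarray, np.ndarray],
                 n_theta: int = 90) -> ParabolicFit:
    """Fit a parabola to a stroke, minimizing the unexplained variance D.

    Nested optimization: for a candidate axis angle the quadratic
    y' = a x'^2 + b x' + c is a closed-form least-squares problem in the
    rotated frame; the axis angle is scanned on a grid over [0, 180) deg
    and refined by bounded scalar minimization.  Both vertex polarities
    come out of the sign of the quadratic coefficient.  The denominator
    of D is the total positional variance of the stroke (invariant to
    rotation/translation), so D is pose-independent.
    """
    if isinstance(stroke, Stroke):
        x, y = stroke.x, stroke.y
    else:
        x, y = np.asarray(stroke[0], float), np.asarray(stroke[1], float)
    if len(x) < 5:
        raise ValueError("stroke must contain at least 5 samples")
    denom = _denominator(x, y)
    if denom <= 0:
        raise ValueError("degenerate: zero positional variance")
    # Collinearity check: smallest PCA eigenvalue.
    cov = np.cov(np.vstack([x, y]))
    evals = np.linalg.eigvalsh(cov)
    if evals[0] < 1e-12 * max(evals[1], 1.0):
        raise ValueError("degenerate: zero curvature (collinear stroke)")

    def d_of_theta(theta: float) -> float:
        out = _quad_fit_in_frame(x, y, theta)
        if out is None or abs(out[0]) < 1e-15:
            return np.inf
        return out[3] / denom

    thetas = np.linspace(0.0, np.pi, n_theta, endpoint=False)
    costs = np.array([d_of_theta(th) for th in thetas])
    i = int(np.argmin(costs))
    span = np.pi / n_theta
    res = minimize_scalar(d_of_theta, bounds=(thetas[i] - span, thetas[i] + span),
                          method="bounded", options={"xatol": 1e-10})
    theta = float(res.x)
    a, b, c, rss, xr, yr = _quad_fit_in_frame(x, y, theta)
    if a < 0:
        # Opening along -y' of this frame: use the frame rotated by 180 deg.
        theta = theta + np.pi
        a, b, c, rss, xr, yr = _quad_fit_in_frame(x, y, theta)
    p = 1.0 / (2.0 * a)
    xv = -b / (2.0 * a)
    yv = c - b**2 / (4.0 * a)
    ct, st = np.cos(theta), np.sin(theta)
    # Frame -> world: world = R(theta) @ frame where R undoes the -theta rotation.
    vertex = (ct * xv - st * yv, st * xv + ct * yv)
    # The parabola opens along +y'; the outward normal at the vertex is -y'.
    normal_world = (st, -ct)
    orientation = float(np.degrees(np.arctan2(normal_world[1], normal_world[0])) % 360.0)
    length = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    return ParabolicFit(p=float(p), orientation=orientation,
                        vertex=(float(vertex[0]), float(vertex[1])),
                        D=rss / denom, euclidean_length=length)


# ---------------------------------------------------------------------------
# Model comparison by the Schwarz information criterion


def _poly_rss(x, y, order):
    """Best RSS of a rotated-frame polynomial of the given order."""
    def cost(theta):
        ct, st = np.cos(theta), np.sin(theta)
        xr = ct * x + st * y
        yr = -st * x + ct * y
        A = np.vander(xr, order + 1)
        coef, _, rank, _ = np.linalg.lstsq(A, yr, rcond=None)
        if rank < order + 1:
            return np.inf
        return float(np.sum((A @ coef - yr) ** 2))
    thetas = np.linspace(0, np.pi, 60, endpoint=False)
    vals = [cost(th) for th in thetas]
    i = int(np.argmin(vals))
    res = minimize_scalar(cost, bounds=(thetas[i] - np.pi / 60, thetas[i] + np.pi / 60),
                          method="bounded")
    return min(float(res.fun), vals[i])


def _ellipse_rss(x, y):
    """Sampson-distance RSS of a direct least-squares ellipse fit."""
    # Fitzgibbon et al. direct ellipse fit.
    xm, ym = x.mean(), y.mean()
    xc, yc = x - xm, y - ym
    D1 = np.column_stack([xc**2, xc * yc, yc**2])
    D2 = np.column_stack([xc, yc, np.ones_like(xc)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
        M = S1 + S2 @ T
        Cinv = np.array([[0, 0, 0.5], [0, -1.0, 0], [0.5, 0, 0]])
        M = Cinv @ M
        evals, evecs = np.linalg.eig(M)
    except np.linalg.LinAlgError:
        return np.inf
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.where(np.isreal(evals) & (cond > 0))[0]
    if len(ok) == 0:
        return np.inf
    a1 = np.real(evecs[:, ok[0]])
    coef = np.concatenate([a1, T @ a1])  # A,B,C,D,E,F on centered coords
    A_, B_, C_, D_, E_, F_ = coef
    alg = A_ * xc**2 + B_ * xc * yc + C_ * yc**2 + D_ * xc + E_ * yc + F_
    gx = 2 * A_ * xc + B_ * yc + D_
    gy = B_ * xc + 2 * C_ * yc + E_
    grad2 = gx**2 + gy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        samp = alg**2 / grad2
    return float(np.nansum(samp))


def model_selection_sic(stroke: Stroke | tuple[np.ndarray, np.ndarray]) -> list[dict]:
    """Rank {parabola, ellipse, poly3, poly4, poly5} by the Schwarz criterion.

    SIC is computed as n*log(RSS/n) + k*log(n); lower penalized value
    means a better goodness-of-fit vs. simplicity trade-off (the
    best-ranked model is reported first).  Parameter counts: parabola 4
    (orientation, 2 translations, p), ellipse 5, poly-k k+2 (k+1
    coefficients plus orientation).
    """
    if isinstance(stroke, Stroke):
        x, y = stroke.x, stroke.y
    else:
        x, y = np.asarray(stroke[0], float), np.asarray(stroke[1], float)
    n = len(x)
    fit = fit_parabola((x, y))
    denom = _denominator(x, y)
    entries = [("parabola", fit.D * denom, 4)]
    entries.append(("ellipse", _ellipse_rss(x, y), 5))
    for order in (3, 4, 5):
        entries.append((f"poly{order}", _poly_rss(x, y, order), order + 2))
    floor = 1e-12 * max(denom, 1.0)
    out = []
    for name, rss, k in entries:
        if not np.isfinite(rss):
            out.append({"model": name, "rss": rss, "k": k, "sic": np.inf,
                        "note": "singular fit"})
            continue
        sic = n * np.log(max(rss, floor) / n) + k * np.log(n)
        out.append({"model": name, "rss": rss, "k": k, "sic": float(sic)})
    out.sort(key=lambda d: d["sic"])
    return out


# ---------------------------------------------------------------------------
# Clustering of primitives


def cluster_parabolas(fits: list[ParabolicFit], n_clusters: int | None = None,
                      d_threshold: float = 0.25, use_p: bool = True,
                      k_range: tuple[int, int] = (1, 6),
                      seed: int = 0) -> ParabolaClusterModel:
    """Cluster fitted primitives on (orientation, log p).

    Orientation is embedded as (cos, sin) so that wrap-around at 0/360
    degrees is handled; log p (optional via ``use_p``) captures size.
    k-means with silhouette-based selection of k within ``k_range``.
    Fits with D above ``d_threshold`` go to the outlier bin (-1).
    """
    if len(fits) < 10:
        raise ValueError("need at least 10 fits")
    good = np.array([f.D <= d_threshold for f in fits])
    kept = [f for f, g in zip(fits, good) if g]
    if n_clusters is not None and len(kept) < n_clusters:
        raise ValueError("fewer usable fits than clusters")
    th = np.radians([f.orientation for f in kept])
    feats = [np.cos(th), np.sin(th)]
    if use_p:
        logp = np.log([f.p for f in kept])
        scale = max(np.std(logp), 1e-9)
        feats.append((logp - logp.mean()) / scale)
    X = np.column_stack(feats)
    if n_clusters is None:
        best_k, best_s = 1, -np.inf
        lo, hi = k_range
        for k in range(max(2, lo), min(hi, len(kept) - 1) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
            if len(np.unique(km.labels_)) < 2:
                continue
            s = silhouette_score(X, km.labels_)
            if s > best_s:
                best_k, best_s = k, s
        # A near-degenerate cloud: everything in one effective cluster.
        if best_s < 0.7 or np.ptp(X, axis=0).max() < 1e-9:
            best_k = 1
        n_clusters = best_k
    if n_clusters == 1:
        labels = np.zeros(len(kept), dtype=int)
    else:
        labels = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(X).labels_
    assignments = np.full(len(fits), -1, dtype=int)
    assignments[np.flatnonzero(good)] = labels
    mean_or = np.zeros(n_clusters)
    mean_p = np.zeros(n_clusters)
    mean_v = np.zeros((n_clusters, 2))
    circ_var = np.zeros(n_clusters)
    p_var = np.zeros(n_clusters)
    for k in range(n_clusters):
        sel = [f for f, l in zip(kept, labels) if l == k]
        ang = np.radians([f.orientation for f in sel])
        z = np.mean(np.exp(1j * ang))
        mean_or[k] = np.degrees(np.angle(z)) % 360.0
        circ_var[k] = 1.0 - np.abs(z)
        lp = np.log([f.p for f in sel])
        mean_p[k] = np.exp(lp.mean())
        p_var[k] = lp.var()
        mean_v[k] = np.mean([f.vertex for f in sel], axis=0)
    return ParabolaClusterModel(n_clusters=n_clusters, assignments=assignments,
                                mean_orientation=mean_or, mean_p=mean_p,
                                mean_vertex=mean_v, circular_variance=circ_var,
                                p_log_variance=p_var)
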