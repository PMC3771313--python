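"""Parabolic-stroke segmentation, fitting and model selection."""

import numpy as np
import pytest

from scribblekit import parabolas as pb
from scribblekit.kinematics import Trajectory


def _parabola_xy(p=20.0, theta=0.3, n=120):
    """Canonical parabola y'^2-style arc rotated by theta."""
    s = np.linspace(-2.0, 2.0, n)
    u, v = p * s ** 2, 2 * p * s      # axis-aligned parabola
    c, sn = np.cos(theta), np.sin(theta)
    return c * u - sn * v, sn * u + c * v


def test_fit_parabola_exact():
    x, y = _parabola_xy()
    fit = pb.fit_parabola((x, y))
    assert fit.D < 1e-8
    # u = 20 s^2, v = 40 s satisfies v^2 = 4 * 20 * u, so p = 2 * 20
    assert fit.p == pytest.approx(40.0, rel=1e-3)


def test_fit_parabola_rotation_invariant_D():
    for theta in (0.0, 0.7, 2.1):
        x, y = _parabola_xy(theta=theta)
        assert pb.fit_parabola((x, y)).D < 1e-8


def test_fit_parabola_nonzero_D_on_circle():
    t = np.linspace(0.2, np.pi - 0.2, 100)
    x, y = 30 * np.cos(t), 30 * np.sin(t)
    assert pb.fit_parabola((x, y)).D > 1e-3


def test_segment_strokes_on_scribble(scribble_traj):
    strokes = pb.segment_strokes_curvature(scribble_traj)
    assert len(strokes) >= 10
    # segments of a noiseless parabolic scribble fit parabolas closely
    Ds = []
    for s in strokes:
        try:
            Ds.append(pb.fit_parabola(s).D)
        except ValueError:
            continue
    assert np.median(Ds) < 1e-3


def test_model_selection_prefers_parabola(scribble_traj):
    strokes = pb.segment_strokes_curvature(scribble_traj)
    ranked = pb.model_selection_sic(strokes[len(strokes) // 2])
    assert ranked[0]["model"] == "parabola"


def test_cluster_parabolas_groups_by_p():
    rng = np.random.default_rng(0)
    fits = []
    for p_true in (5.0, 500.0):
        for _ in range(20):
            x, y = _parabola_xy(p=p_true * rng.uniform(0.95, 1.05),
                                theta=0.3)
            fits.append(pb.fit_parabola((x, y)))
    model = pb.cluster_parabolas(fits, n_clusters=2, seed=0)
    labels = np.asarray(model.assignments)
    first, second = labels[:20], labels[20:]
    assert np.all(first == first[0])
    assert np.all(second == second[0])
    assert first[0] != second[0]


def test_fit_parabola_rejects_degenerate():
    x = np.linspace(0, 1, 30)
    with pytest.raises(ValueError):
        pb.fit_parabola((x, np.zeros_like(x)))
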