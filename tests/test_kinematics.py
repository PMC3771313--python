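"""Equi-affine kinematics and the two-thirds power law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scribblekit import kinematics as km


def test_differentiate_recovers_velocity(parabola_traj):
    prof = km.differentiate(parabola_traj)
    # interior samples of a polynomial trajectory: exact derivatives
    sl = slice(20, -20)
    vx_true = 120.0 - 60.0 * parabola_traj.t
    vy_true = 40.0 + 90.0 * parabola_traj.t
    assert np.allclose(prof.vx[sl], vx_true[sl], rtol=1e-3, atol=1e-2)
    assert np.allclose(prof.vy[sl], vy_true[sl], rtol=1e-3, atol=1e-2)


def test_equi_affine_speed_cube_law(parabola_traj):
    """sigma-dot^3 = |vx*ay - vy*ax| pointwise."""
    prof = km.differentiate(parabola_traj)
    sl = slice(20, -20)
    cross = np.abs(prof.vx * prof.ay - prof.vy * prof.ax)
    assert np.allclose(prof.ea_speed[sl] ** 3, cross[sl], rtol=1e-2)


def test_power_law_beta_on_parabola(parabola_traj):
    prof = km.differentiate(parabola_traj)
    fit = km.power_law_fit(prof)
    assert fit.beta == pytest.approx(2.0 / 3.0, abs=1e-3)
    assert fit.r2 > 0.999


def test_power_law_requires_samples(parabola_traj):
    prof = km.differentiate(parabola_traj)
    with pytest.raises(ValueError):
        km.power_law_fit(prof, mask=np.zeros(prof.vx.size, dtype=bool))


def test_equi_affine_curvature_zero_on_parabola(parabola_traj):
    kappa, _ = km.equi_affine_curvature(parabola_traj)
    interior = kappa[np.isfinite(kappa)][10:-10]
    assert np.nanmax(np.abs(interior)) < 1e-2


def test_circle_has_positive_constant_ea_curvature():
    t = np.arange(0, 2 * np.pi, 0.01)
    traj = km.Trajectory(t=t, x=50 * np.cos(t), y=50 * np.sin(t))
    kappa, _ = km.equi_affine_curvature(traj)
    interior = kappa[np.isfinite(kappa)][20:-20]
    # a circle of radius R has equi-affine curvature R^(-4/3)
    assert np.allclose(interior, 50.0 ** (-4 / 3), rtol=0.05)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.2, 3.0), st.floats(-1.5, 1.5), st.floats(-1.5, 1.5),
       st.floats(-80.0, 80.0), st.floats(-80.0, 80.0))
def test_ea_curvature_invariant_under_det1_maps(a, b, c, e, f):
    """Equi-affine curvature is invariant under det-1 affine maps."""
    t = np.arange(0.0, 1.5, 0.01)
    traj = km.Trajectory(t=t, x=100 * t + 30 * t ** 2, y=60 * t - 45 * t ** 2)
    ee = (1.0 + b * c) / a  # forces a*e - b*c = 1 (linear part det 1)
    mapped = km.equi_affine_transform(traj, a, b, e, c, ee, f)
    k0, _ = km.equi_affine_curvature(traj)
    k1, _ = km.equi_affine_curvature(mapped)
    sl = slice(15, -15)
    assert np.allclose(np.nan_to_num(k0[sl]), np.nan_to_num(k1[sl]),
                       atol=1e-2)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.5, 2.0), st.floats(-1.0, 1.0))
def test_ea_speed_invariant_under_det1_maps(a, b):
    t = np.arange(0.0, 1.5, 0.01)
    traj = km.Trajectory(t=t, x=100 * t + 30 * t ** 2, y=60 * t - 45 * t ** 2)
    mapped = km.equi_affine_transform(traj, a, b, 5.0, 0.0, 1.0 / a, -3.0)
    s0 = km.equi_affine_speed(km.differentiate(traj))
    s1 = km.equi_affine_speed(km.differentiate(mapped))
    sl = slice(15, -15)
    assert np.allclose(s0[sl], s1[sl], rtol=1e-6, atol=1e-9)


def test_trajectory_validation_rejects_bad_shapes():
    with pytest.raises(ValueError):
        km.Trajectory(t=np.arange(3.0), x=np.arange(4.0), y=np.arange(3.0))
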