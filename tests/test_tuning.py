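"""Delay-grid rate regression: recovering planted tuning delays."""

import numpy as np
import pytest

from scribblekit import kinematics as km
from scribblekit import synthgen, tuning


@pytest.fixture(scope="module")
def long_scribble():
    """120 s irregular scribble with enough speed variation for fitting."""
    spec = synthgen.velocity_cycle_spec(
        n_segments=240, radii=np.array([1.0, 0.7, 1.3]),
        waypoint_jitter=40.0, seed=11)
    traj, _ = synthgen.gen_parabolic_scribble(spec)
    return traj, km.differentiate(traj)


def test_rate_estimate_mean_matches_count():
    st = np.sort(np.random.default_rng(0).uniform(0, 50, 400))
    rs = tuning.rate_estimate(st, duration=50.0)
    assert np.trapezoid(rs.rate, rs.t) == pytest.approx(400, rel=0.05)


def test_velocity_delay_recovered(long_scribble):
    traj, prof = long_scribble
    spec = synthgen.TuningSpec(units=[
        {"baseline": 20.0, "velocity": [0.04, 0.02], "velocity_delay": 0.07}])
    spikes, _ = synthgen.gen_tuned_spike_trains(traj, spec, seed=0)
    rate = tuning.rate_estimate(spikes.spike_times(0), traj.duration)
    cube = tuning.delay_regression_pva(rate, traj, prof)
    (d_pos, d_vel, d_acc), r2 = cube.best()
    assert d_vel == pytest.approx(0.07, abs=0.01)
    assert r2 > 0.05


def test_partial_contribution_flags_velocity(long_scribble):
    traj, prof = long_scribble
    spec = synthgen.TuningSpec(units=[
        {"baseline": 20.0, "velocity": [0.04, 0.02], "velocity_delay": 0.07}])
    spikes, _ = synthgen.gen_tuned_spike_trains(traj, spec, seed=0)
    rate = tuning.rate_estimate(spikes.spike_times(0), traj.duration)
    res = tuning.partial_contribution(rate, traj, prof, "velocity")
    assert res.dominant
    assert res.dominant_lag == pytest.approx(0.07, abs=0.01)


def test_speed_model_identifies_equi_affine(long_scribble):
    traj, prof = long_scribble
    spec = synthgen.TuningSpec(units=[
        {"baseline": 15.0, "ea_speed": [0.3], "ea_speed_delay": 0.12}])
    spikes, _ = synthgen.gen_tuned_spike_trains(traj, spec, seed=1)
    rate = tuning.rate_estimate(spikes.spike_times(0), traj.duration)
    res = tuning.speed_model_fit(rate, traj, prof, n_perm=100, seed=0)
    assert res["ea_dominant"]
    # sigma-dot is piecewise constant per stroke, so the recoverable lag
    # resolution is coarse
    assert res["ea_lag"] == pytest.approx(0.12, abs=0.05)
    assert res["p_value"] < 0.05


def test_untuned_unit_is_not_significant(long_scribble):
    traj, prof = long_scribble
    spikes = synthgen.gen_poisson_trains(1, rate=20.0,
                                         duration=traj.duration, seed=5)
    rate = tuning.rate_estimate(spikes.spike_times(0), traj.duration)
    res = tuning.speed_model_fit(rate, traj, prof, n_perm=100, seed=0)
    assert res["p_value"] > 0.05


def test_dominant_stripe_rule():
    vals = np.zeros((5, 5))
    vals[2, :] = 1.0                      # a clean row stripe
    dom, lag = tuning.dominant_stripe(vals, axis=0,
                                      delays=np.linspace(-0.1, 0.1, 5))
    assert dom
    assert lag == pytest.approx(0.0)
    # a diagonal has no stripe with half its cells above half-max
    assert not tuning.dominant_stripe(np.eye(5), axis=0)[0]


def test_delay_regression_requires_long_record():
    t = np.arange(0, 10.0, 0.01)
    traj = km.Trajectory(t=t, x=np.sin(t), y=np.cos(t))
    prof = km.differentiate(traj)
    rate = tuning.rate_estimate(np.array([1.0, 2.0]), 10.0)
    with pytest.raises(ValueError):
        tuning.delay_regression_pva(rate, traj, prof)
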