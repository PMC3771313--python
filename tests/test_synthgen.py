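"""Synthetic data generators: ground-truth consistency and reproducibility."""

import numpy as np
import pytest

from scribblekit import kinematics as km
from scribblekit import synthgen
from scribblekit.parabolas import fit_parabola


def test_scribble_is_reproducible():
    spec = synthgen.velocity_cycle_spec(n_segments=10, seed=3)
    t1, _ = synthgen.gen_parabolic_scribble(spec)
    t2, _ = synthgen.gen_parabolic_scribble(spec)
    assert np.array_equal(t1.x, t2.x)


def test_scribble_segments_match_truth(scribble):
    traj, truth = scribble
    labels = truth["labels"]
    # each contiguous segment fits a parabola whose p matches its ledger
    for seg in truth["segments"][2:6]:
        sel = labels == seg["segment"]
        fit = fit_parabola((traj.x[sel], traj.y[sel]))
        assert fit.D < 1e-6
        assert fit.p == pytest.approx(seg["p"], rel=0.05)


def test_scribble_obeys_power_law(scribble_traj):
    prof = km.differentiate(scribble_traj)
    fit = km.power_law_fit(prof)
    assert fit.beta == pytest.approx(2.0 / 3.0, abs=0.01)


def test_tuned_trains_rate_scales_with_coefficient(scribble_traj):
    spec = synthgen.TuningSpec(units=[
        {"baseline": 5.0, "euclid_speed": [0.0]},
        {"baseline": 5.0, "euclid_speed": [0.05]},
    ])
    spikes, truth = synthgen.gen_tuned_spike_trains(scribble_traj, spec, seed=0)
    r0 = len(spikes.spike_times(0)) / spikes.duration
    r1 = len(spikes.spike_times(1)) / spikes.duration
    assert r0 == pytest.approx(5.0, rel=0.25)
    assert r1 > r0 + 3.0


def test_markov_trains_rates_match_occupancy():
    P = np.array([[0.95, 0.05], [0.05, 0.95]])
    Lambda = np.array([[20.0], [2.0]])
    spikes, path = synthgen.gen_markov_spike_trains(
        2, 1, P, Lambda, duration=200.0, seed=4)
    dt = 0.05
    expected = (Lambda[path, 0] * dt).sum()
    assert len(spikes.spike_times(0)) == pytest.approx(expected, rel=0.1)


def test_markov_trains_reject_bad_transition_matrix():
    with pytest.raises(ValueError):
        synthgen.gen_markov_spike_trains(
            2, 1, np.array([[0.5, 0.4], [0.5, 0.5]]), np.ones((2, 1)), 10.0)


def test_embed_precise_patterns_plants_exact_pairs():
    base = synthgen.gen_poisson_trains(4, rate=3.0, duration=100.0, seed=2,
                                       electrodes=[0, 1, 2, 3])
    occurrences = np.arange(5.0, 95.0, 5.0)
    plant = synthgen.PlantSpec(n1=0, n2=1, delta=0.02)
    planted, ledger = synthgen.embed_precise_patterns(base, occurrences,
                                                      [plant], seed=0)
    assert len(ledger["insertions"]) + ledger["skipped"] == len(occurrences)
    for ins in ledger["insertions"]:
        assert ins["t2"] - ins["t1"] == pytest.approx(0.02, abs=1e-12)
        assert np.any(np.isclose(planted.spike_times(0), ins["t1"]))
        assert np.any(np.isclose(planted.spike_times(1), ins["t2"]))


def test_embed_rejects_same_electrode_pair():
    base = synthgen.gen_poisson_trains(2, rate=3.0, duration=10.0, seed=0,
                                       electrodes=[0, 0])
    with pytest.raises(ValueError):
        synthgen.embed_precise_patterns(
            base, np.array([5.0]), [synthgen.PlantSpec(n1=0, n2=1, delta=0.01)])


def test_syntax_trajectory_truth_shapes():
    traj, truth = synthgen.gen_syntax_trajectory(n_strokes=50, seed=1)
    assert len(truth["word"]) == len(traj)
    assert truth["n_words"] == 3
    assert set(np.unique(truth["word"])) <= {0, 1, 2}
    assert set(np.unique(truth["accel"])) == {0, 1}
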