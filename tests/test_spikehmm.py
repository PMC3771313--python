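"""Hidden-Markov modelling of multi-unit firing-rate states."""

import numpy as np
import pytest

from scribblekit import spikehmm as hm
from scribblekit import synthgen


def _three_state_setup(duration=120.0, seed=0, stay=0.9):
    N, M = 3, 6
    P = np.full((N, N), (1.0 - stay) / 2)
    np.fill_diagonal(P, stay)
    Lambda = np.full((N, M), 2.0)
    for k in range(N):
        Lambda[k, k::N] = 12.0
    spikes, path = synthgen.gen_markov_spike_trains(
        N, M, P, Lambda, duration=duration, seed=seed)
    return N, M, P, Lambda, spikes, path


def test_bin_spikes_counts_are_consistent():
    spikes = synthgen.gen_poisson_trains(4, rate=10.0, duration=20.0, seed=1)
    counts = hm.bin_spikes(spikes, dt=0.05)
    assert counts.counts.shape == (400, 4)
    total = sum(len(u["spike_times"]) for u in spikes.units)
    assert counts.counts.sum() == total


def test_changepoints_fall_near_true_flips():
    _, _, _, _, spikes, path = _three_state_setup()
    counts = hm.bin_spikes(spikes, dt=0.05)
    cps, mll = hm.mll_changepoints(counts, mode="top_fraction")
    true_flips = np.flatnonzero(np.diff(path)) * 0.05
    assert len(cps) >= 10
    # a majority of detected changepoints lie within 0.2 s of a true flip
    near = [np.min(np.abs(true_flips - c)) < 0.2 for c in cps]
    assert np.mean(near) > 0.5


@pytest.fixture(scope="module")
def fitted_hmm():
    """One EM fit on 300 s of three-state data, shared across tests."""
    N, M, P, Lambda, spikes, path = _three_state_setup(duration=300.0,
                                                       stay=0.95)
    counts = hm.bin_spikes(spikes, dt=0.05)
    cps, _ = hm.mll_changepoints(counts, mode="top_fraction")
    init = hm.init_hmm(counts, cps, N, seed=0)
    model, trace = hm.baum_welch(counts, init)
    return dict(counts=counts, init=init, model=model, trace=trace,
                Lambda=Lambda, path=path)


def test_baum_welch_increases_likelihood_and_recovers_rates(fitted_hmm):
    one_step, _ = hm.baum_welch(fitted_hmm["counts"], fitted_hmm["init"],
                                max_iter=1)
    model = fitted_hmm["model"]
    assert model.log_likelihood >= one_step.log_likelihood
    perm = hm.match_states(model.Lambda, fitted_hmm["Lambda"])
    rel = np.abs(model.Lambda[perm] - fitted_hmm["Lambda"]) / fitted_hmm["Lambda"]
    assert np.all(rel < 0.2)


def test_viterbi_matches_true_path(fitted_hmm):
    perm = hm.match_states(fitted_hmm["model"].Lambda, fitted_hmm["Lambda"])
    inv = np.argsort(perm)
    assert np.mean(inv[fitted_hmm["trace"].viterbi_path]
                   == fitted_hmm["path"]) > 0.9


def test_match_states_identity_and_permutation():
    Lambda = np.array([[1.0, 9.0], [9.0, 1.0]])
    assert list(hm.match_states(Lambda, Lambda)) == [0, 1]
    assert list(hm.match_states(Lambda[::-1], Lambda)) == [1, 0]


def test_init_hmm_rejects_too_few_segments():
    spikes = synthgen.gen_poisson_trains(3, rate=8.0, duration=10.0, seed=0)
    counts = hm.bin_spikes(spikes, dt=0.05)
    with pytest.raises(ValueError):
        hm.init_hmm(counts, np.array([5.0]), N=5)


def test_hmm_model_validation():
    with pytest.raises(ValueError):
        hm.HmmModel(P=np.array([[0.5, 0.4], [0.5, 0.5]]),
                    Lambda=np.ones((2, 3)), pi=np.array([0.5, 0.5]),
                    dt=0.05).validate()
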