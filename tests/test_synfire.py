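"""Balanced network with embedded chains: build, simulate, decode."""

import numpy as np
import pytest

from scribblekit import synfire as sf


def test_cycle_chain_specs_structure():
    chains = sf.cycle_chain_specs(3, width=100, radii=[1.0, 0.7, 1.3])
    assert len(chains) == 3
    for ch in chains:
        assert ch.width == 100
        pv = ch.pool_velocities()
        assert pv.shape == (ch.length, 2)
    # successors form a single 3-cycle
    succ = [ch.successors for ch in chains]
    assert all(len(s) == 1 for s in succ)
    assert sorted(s[0] for s in succ) == [0, 1, 2]


def test_velocity_graph_closed_cycle():
    chains = sf.cycle_chain_specs(3)
    g = sf.build_velocity_graph(chains)
    # each chain's net displacement arrow ends where the next begins
    total = sum(ch.pool_velocities().sum(axis=0) for ch in chains)
    assert np.allclose(total, 0.0, atol=1e-9 * 300 * 30)


def test_psc_weight_sign_and_scale():
    w_exc = sf.psc_weight_for_psp(0.1e-3, 0.2e-3)
    w_big = sf.psc_weight_for_psp(0.5e-3, 0.2e-3)
    assert w_exc > 0
    assert w_big == pytest.approx(5 * w_exc)


def test_network_build_sizes_and_audit():
    cfg = sf.scribbler_config()
    net = sf.build_network(cfg, seed=0)
    n_chain = sum(ch.width * ch.length for ch in cfg.chains)
    assert net.n >= cfg.n_exc + cfg.n_inh
    assert sum(m.size for m in net.membership) == n_chain
    audit = net.audit()
    assert audit["n_synapses"] > 0


def test_run_length_stats_geometric_accept_constant_reject():
    rng = np.random.default_rng(0)
    geo = rng.geometric(0.4, size=300) - 1
    res = sf.run_length_stats(geo)
    assert not res["reject"]
    assert res["p0"] == pytest.approx(0.4, abs=0.06)
    const = np.full(300, 3)
    assert sf.run_length_stats(const)["reject"]
    with pytest.raises(ValueError):
        sf.run_length_stats([0, 1, 2])


@pytest.fixture(scope="module")
def short_sim():
    cfg = sf.scribbler_config()
    net = sf.build_network(cfg, seed=0)
    raster = sf.simulate(net, duration=1.0, seed=1)
    return net, raster


def test_simulation_background_is_irregular(short_sim):
    net, raster = short_sim
    # ISI irregularity of background excitatory neurons not in any chain
    chain_ids = np.concatenate([m.ravel() for m in net.membership])
    bg = np.setdiff1d(np.arange(2000), chain_ids)[:300]
    cvs = []
    for i in bg:
        st = raster.times[raster.neuron_ids == i]
        if len(st) >= 5:
            isi = np.diff(st)
            cvs.append(isi.std() / isi.mean())
    assert np.median(cvs) > 0.5


def test_stimulated_chain_produces_complete_runs(short_sim):
    net, raster = short_sim
    runs = sf.detect_chain_runs(raster, net)
    assert any(r["complete"] for r in runs)


def test_decoded_velocity_follows_active_chain(short_sim):
    net, raster = short_sim
    dec = sf.decode_trajectory(raster, net, smooth=8e-3)
    assert dec.v.shape == (len(dec.t), 2)
    active = dec.active_chain >= 0
    assert active.any()
    # while decoding is active, speed is of the order of the preferred
    # speeds (300 mm/s scale)
    sp = np.hypot(dec.v[active, 0], dec.v[active, 1])
    assert 50.0 < np.median(sp) < 600.0
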