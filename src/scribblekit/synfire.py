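"""Spiking-network generator of parabolic scribbles.

A balanced network of leaky integrate-and-fire neurons whose
excitatory-to-excitatory connectivity consists entirely of embedded
synfire chains.  Each chain is mapped onto a straight arrow in velocity
space: pool ``i`` of a chain is assigned the preferred velocity obtained
by linear interpolation between the chain's start and end velocities.  A
spike volley propagating along a chain therefore traces a straight line
in velocity space, which integrates to a parabola in position space —
constant acceleration.  Chains are wired head-to-tail (the end velocity
of one equals the start velocity of its successors), so sustained volley
propagation draws a scribble of concatenated parabolic strokes.

The simulator uses exact integration of the linear membrane/synapse
dynamics (alpha-shaped postsynaptic currents) on a fixed time grid.
Population decoding of the raster (a normalized population vector over
pool activities) recovers the drawn trajectory; run statistics quantify
how long uninterrupted volley propagation survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.ndimage import gaussian_filter1d
from scipy.stats import chi2

from .kinematics import Trajectory

__all__ = [
    "NeuronParams",
    "ChainSpec",
    "NetworkConfig",
    "VelocityGraph",
    "Network",
    "Raster",
    "DecodedTrajectory",
    "build_velocity_graph",
    "cycle_chain_specs",
    "build_network",
    "scribbler_config",
    "ai_background_config",
    "simulate",
    "detect_chain_runs",
    "run_sequences",
    "decode_trajectory",
    "run_length_stats",
    "psc_weight_for_psp",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron with alpha-current synapses.

    All values in SI units, expressed relative to the resting potential
    (resting = 0, threshold ``theta`` above it; reset back to rest).
    """

    tau_m: float = 0.020        # membrane time constant, s
    capacitance: float = 250e-12  # F
    theta: float = 0.020        # spike threshold, V
    t_ref: float = 0.002        # absolute refractory period, s
    v_reset: float = 0.0        # V
    tau_syn_exc: float = 0.2e-3  # alpha-current rise time, excitatory, s
    tau_syn_inh: float = 0.6e-3  # alpha-current rise time, inhibitory, s

    def __post_init__(self):
        for name in ("tau_m", "capacitance", "theta", "t_ref",
                     "tau_syn_exc", "tau_syn_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ChainSpec:
    """A synfire chain mapped onto a velocity-space arrow."""

    width: int                  # neurons per pool (w)
    length: int                 # number of pools (l)
    v_start: tuple[float, float]  # mm/s
    v_end: tuple[float, float]    # mm/s
    p_d: float = 0.75           # feed-forward dilution
    successors: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("a chain needs at least 2 pools")
        if not 0 < self.p_d <= 1:
            raise ValueError("dilution must be in (0, 1]")
        if len(self.successors) > 2:
            raise ValueError("at most 2 successors per chain")

    def pool_velocities(self) -> np.ndarray:
        """Preferred velocity of each pool: linear interpolation from
        ``v_start`` to ``v_end`` (pool i at (i-1)/(n-1) of the way)."""
        f = np.linspace(0.0, 1.0, self.length)[:, None]
        v0 = np.asarray(self.v_start, dtype=float)
        v1 = np.asarray(self.v_end, dtype=float)
        return (1 - f) * v0 + f * v1


@dataclass
class NetworkConfig:
    """Sizes, synaptic amplitudes and drive of the scribbler network."""

    n_exc: int
    n_inh: int
    chains: list[ChainSpec]
    neuron: NeuronParams = field(default_factory=NeuronParams)
    epsp_bg: float = 0.1e-3     # background EPSP amplitude, V
    epsp_chain: float = 0.5e-3  # feed-forward EPSP within chains, V
    ipsp_factor: float = 6.0    # IPSP amplitude = factor x epsp_bg
    conn_prob_bg: float = 0.1   # E->I connection probability
    conn_prob_inh: float | None = None  # I->I, I->E probability (default: bg)
    delay_range: tuple[float, float] = (0.5e-3, 3e-3)  # s; shared per pool pair
    dc_drive: float = 350e-12   # A, all neurons
    nu_ext: float = 0.0         # Hz, per-neuron external Poisson drive
    ext_psp: float = 0.5e-3     # V, EPSP of one external drive spike
    p_ce: float = 0.75          # last pool -> successor first pool dilution
    k_c: int = 20               # cross-inhibition synapses per relay neuron
    stim_rate: float = 1.0      # Hz, ignition stimulation of chain 0
    stim_spikes: int = 100      # spikes per stimulus packet
    stim_sigma: float = 1e-3    # s, packet dispersion
    # backward-and-forward connected chain (BFC) for self-re-ignition:
    # while any chain carries volleys, a global-inhibition relay group
    # driven by every chain pool clamps the BFC; when activity dies out
    # the BFC is disinhibited, self-ignites and re-triggers chain 0
    bfc_width: int = 0          # 0 disables the BFC
    bfc_length: int = 10
    k_g: int = 6                # global-inhibition relay neurons per pool
    k_b: int = 1000             # synapses from each relay onto the BFC
    bfc_self_clamp: int = 20    # delayed self-inhibition relays: turn BFC
    #                             saturation into short ignition bursts
    bfc_drive: float = 1.1      # external-drive multiplier for BFC neurons


@dataclass
class VelocityGraph:
    """Validated successor structure with per-pool preferred velocities."""

    chains: list[ChainSpec]
    pool_velocities: list[np.ndarray]


@dataclass
class Raster:
    """Spikes of a simulation: parallel arrays of neuron ids and times."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class DecodedTrajectory:
    """Population-decoded movement with the active chain per bin."""

    t: np.ndarray               # bin centers, s
    v: np.ndarray               # (n, 2) mm/s
    position: np.ndarray        # (n, 2) mm, cumulative integral of v
    active_chain: np.ndarray    # int per bin, -1 when silent

    def trajectory(self) -> Trajectory:
        return Trajectory(t=self.t, x=self.position[:, 0],
                          y=self.position[:, 1])


# ---------------------------------------------------------------------------
# Velocity graph
# ---------------------------------------------------------------------------

def build_velocity_graph(chains: list[ChainSpec],
                         atol: float = 1e-9) -> VelocityGraph:
    """Validate the successor structure: the velocity at the end of one
    stroke equals the velocity at the beginning of the next."""
    for i, ch in enumerate(chains):
        for s in ch.successors:
            if not 0 <= s < len(chains):
                raise ValueError(f"chain {i}: successor {s} out of range")
            if not np.allclose(ch.v_end, chains[s].v_start, atol=atol):
                raise ValueError(
                    f"chain {i} ends at {ch.v_end} but successor {s} "
                    f"starts at {chains[s].v_start}")
    return VelocityGraph(chains=chains,
                         pool_velocities=[c.pool_velocities() for c in chains])


def cycle_chain_specs(n_chains: int = 3, speed: float = 300.0,
                      width: int = 50, length: int = 20,
                      p_d: float = 0.75,
                      radii: np.ndarray | None = None) -> list[ChainSpec]:
    """A closed cycle of chains whose velocity arrows form a polygon
    (chain k runs from vertex k to vertex k+1 and its successor is the
    next chain), the network analogue of a repeating scribble cycle."""
    ang = 2 * np.pi * np.arange(n_chains) / n_chains + np.pi / n_chains
    r = np.ones(n_chains) if radii is None else np.asarray(radii, dtype=float)
    pts = speed * r[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
    chains = []
    for k in range(n_chains):
        chains.append(ChainSpec(
            width=width, length=length,
            v_start=tuple(pts[k]), v_end=tuple(pts[(k + 1) % n_chains]),
            p_d=p_d, successors=[(k + 1) % n_chains]))
    return chains


# ---------------------------------------------------------------------------
# Exact integration machinery
# ---------------------------------------------------------------------------

def _propagator(p: NeuronParams, dt: float) -> np.ndarray:
    """Exact one-step propagator of the linear subthreshold dynamics.

    State: [y1e, y2e, y1i, y2i, V] where each (y1, y2) pair realizes an
    alpha-shaped current (a kick to y1 makes y2 trace an alpha function)
    and V integrates y2e + y2i through the membrane.
    """
    a = np.zeros((5, 5))
    te, ti, tm, c = p.tau_syn_exc, p.tau_syn_inh, p.tau_m, p.capacitance
    a[0, 0] = -1 / te
    a[1, 0], a[1, 1] = 1.0, -1 / te
    a[2, 2] = -1 / ti
    a[3, 2], a[3, 3] = 1.0, -1 / ti
    a[4, 1] = 1 / c
    a[4, 3] = 1 / c
    a[4, 4] = -1 / tm
    return expm(a * dt)


def psc_weight_for_psp(amp: float, tau_syn: float,
                       p: NeuronParams | None = None,
                       dt: float = 0.02e-3, horizon: float = 0.03) -> float:
    """Postsynaptic-current kick producing a peak membrane deflection of
    ``amp`` volts for an alpha current with rise time ``tau_syn``.

    The kick is the value added to y1 at spike arrival; the resulting y2
    is the alpha-shaped current and the peak of the V response is found
    numerically from the exact propagator.
    """
    p = p or NeuronParams()
    sub = NeuronParams(tau_m=p.tau_m, capacitance=p.capacitance,
                       theta=p.theta, t_ref=p.t_ref,
                       tau_syn_exc=tau_syn, tau_syn_inh=p.tau_syn_inh)
    prop = _propagator(sub, dt)
    state = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    vmax = 0.0
    for _ in range(int(horizon / dt)):
        state = prop @ state
        vmax = max(vmax, state[4])
    if vmax <= 0:
        raise RuntimeError("degenerate synaptic response")
    return amp / vmax


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

class Network:
    """A built scribbler network: connectivity in CSR form, chain pool
    memberships, and everything `simulate` needs."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.n_bfc = config.bfc_width * config.bfc_length \
            if config.bfc_width > 0 else 0
        self.n_relay = (config.k_g
                        * sum(ch.length for ch in config.chains)
                        + config.bfc_self_clamp
                        if self.n_bfc > 0 else 0)
        self.n = config.n_exc + config.n_inh + self.n_bfc + self.n_relay
        self._build(np.random.default_rng(seed))

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        p = cfg.neuron
        graph = build_velocity_graph(cfg.chains)
        self.pool_velocities = graph.pool_velocities

        w_bg = psc_weight_for_psp(cfg.epsp_bg, p.tau_syn_exc, p)
        w_chain = psc_weight_for_psp(cfg.epsp_chain, p.tau_syn_exc, p)
        w_inh = -cfg.ipsp_factor * psc_weight_for_psp(
            cfg.epsp_bg, p.tau_syn_inh, p)

        # chain memberships: a neuron occupies at most one position per
        # chain but may belong to several chains.  Chains are drawn from
        # the not-yet-used excitatory neurons while capacity lasts (less
        # cross-chain interference); once exhausted, neurons are shared.
        self.membership: list[np.ndarray] = []
        unused = rng.permutation(cfg.n_exc).tolist()
        for ci, ch in enumerate(cfg.chains):
            need = ch.width * ch.length
            if need > cfg.n_exc:
                raise ValueError(
                    f"chain {ci} needs {need} distinct excitatory neurons "
                    f"but only {cfg.n_exc} exist")
            if len(unused) >= need:
                picks = np.array(unused[:need])
                del unused[:need]
            else:
                picks = rng.choice(cfg.n_exc, size=need, replace=False)
            self.membership.append(picks.reshape(ch.length, ch.width))

        pre, post, wgt, dly, inh = [], [], [], [], []

        def connect_pools(src: np.ndarray, dst: np.ndarray, prob: float,
                          weight: float, delay: float) -> None:
            mask = rng.uniform(size=(src.size, dst.size)) < prob
            i, j = np.nonzero(mask)
            pre.append(src[i])
            post.append(dst[j])
            wgt.append(np.full(i.size, weight))
            dly.append(np.full(i.size, delay))
            inh.append(np.zeros(i.size, dtype=bool))

        lo, hi = cfg.delay_range
        for ci, ch in enumerate(cfg.chains):
            pools = self.membership[ci]
            for k in range(ch.length - 1):
                connect_pools(pools[k], pools[k + 1], ch.p_d, w_chain,
                              rng.uniform(lo, hi))
            for s in ch.successors:
                connect_pools(pools[-1], self.membership[s][0], cfg.p_ce,
                              w_chain, rng.uniform(lo, hi))

        # competitive cross-inhibition between sibling successors: the
        # early pools of each competitor drive a private inhibitory relay
        # that suppresses the rival chain
        inh_cursor = 0
        for ch in cfg.chains:
            if len(ch.successors) < 2:
                continue
            for a in ch.successors:
                rivals = [b for b in ch.successors if b != a]
                relay = np.arange(inh_cursor,
                                  inh_cursor + cfg.k_c) % cfg.n_inh + cfg.n_exc
                inh_cursor += cfg.k_c
                src = self.membership[a][:3].ravel()
                for s in src:
                    pre.append(np.full(relay.size, s))
                    post.append(relay)
                    wgt.append(np.full(relay.size, w_chain))
                    dly.append(np.full(relay.size, lo))
                    inh.append(np.zeros(relay.size, dtype=bool))
                for b in rivals:
                    tgt = self.membership[b][:6].ravel()
                    for r in relay:
                        pre.append(np.full(tgt.size, r))
                        post.append(tgt)
                        wgt.append(np.full(tgt.size, 4 * w_inh))
                        dly.append(np.full(tgt.size, lo))
                        inh.append(np.ones(tgt.size, dtype=bool))

        # balanced background: E->I, I->I, I->E with connection
        # probability conn_prob_bg; the E->E subnetwork is purely the
        # synfire chains
        def random_block(src0, src1, dst0, dst1, weight, is_inh,
                         prob=cfg.conn_prob_bg):
            n_src, n_dst = src1 - src0, dst1 - dst0
            k = rng.binomial(n_src, prob, size=n_dst)
            tot = int(k.sum())
            s = rng.integers(src0, src1, size=tot)
            d = np.repeat(np.arange(dst0, dst1), k)
            pre.append(s)
            post.append(d)
            wgt.append(np.full(tot, weight))
            dly.append(rng.uniform(lo, hi, size=tot))
            inh.append(np.full(tot, is_inh))

        ne, ni_end = cfg.n_exc, cfg.n_exc + cfg.n_inh
        p_inh = cfg.conn_prob_inh if cfg.conn_prob_inh is not None \
            else cfg.conn_prob_bg
        random_block(0, ne, ne, ni_end, w_bg, False)             # E -> I
        random_block(ne, ni_end, ne, ni_end, w_inh, True, p_inh)  # I -> I
        random_block(ne, ni_end, 0, ne, w_inh, True, p_inh)       # I -> E

        # BFC: a backward-and-forward connected chain beyond the main
        # populations, clamped by a global-inhibition relay group that is
        # driven by every chain pool, and wired into chain 0's first pool
        self.drive_scale = np.ones(self.n)
        self.bfc_pools = None
        if self.n_bfc > 0:
            base = ni_end
            self.bfc_pools = np.arange(
                base, base + self.n_bfc).reshape(cfg.bfc_length, cfg.bfc_width)
            self.drive_scale[base:base + self.n_bfc] = cfg.bfc_drive
            # the BFC sits in the same balanced background as the chains:
            # without I->BFC inhibition the external drive alone would
            # saturate it regardless of any clamp
            random_block(ne, ni_end, base, base + self.n_bfc,
                         w_inh, True, p_inh)
            for k in range(cfg.bfc_length - 1):
                d = rng.uniform(lo, hi)
                ch0 = cfg.chains[0]
                connect_pools(self.bfc_pools[k], self.bfc_pools[k + 1],
                              ch0.p_d, w_chain, d)
                connect_pools(self.bfc_pools[k + 1], self.bfc_pools[k],
                              ch0.p_d, w_chain, rng.uniform(lo, hi))
            # ignition handoff into chain 0 is stronger than ordinary
            # feed-forward links: the BFC burst is a few ms wide, so each
            # target neuron needs a larger kick to produce a tight volley
            connect_pools(self.bfc_pools[-1], self.membership[0][0],
                          1.0, 4 * w_chain, rng.uniform(lo, hi))
            # global inhibition: k_g dedicated relay neurons per chain pool
            # (outside the background populations, so their volleys touch
            # nothing else).  Each relay listens to one pool only — the
            # pool's asynchronous background is subthreshold but its volley
            # discharges the relay — and makes k_b strong inhibitory
            # synapses onto the BFC, clamping it while chains are active
            relays = np.arange(base + self.n_bfc,
                               base + self.n_bfc + self.n_relay)
            # relays get no external drive: silent unless a volley passes
            self.drive_scale[relays] = 0.0
            k_b = min(cfg.k_b, self.n_bfc)
            cursor = 0
            for pools in self.membership:
                for pool in pools:
                    grp = relays[cursor:cursor + cfg.k_g]
                    cursor += cfg.k_g
                    for s in pool[:min(40, pool.size)]:
                        pre.append(np.full(grp.size, s))
                        post.append(grp)
                        wgt.append(np.full(grp.size, w_chain))
                        dly.append(np.full(grp.size, lo))
                        inh.append(np.zeros(grp.size, dtype=bool))
                    for r in grp:
                        tgt = rng.choice(self.n_bfc, k_b,
                                         replace=False) + base
                        pre.append(np.full(k_b, r))
                        post.append(tgt)
                        wgt.append(np.full(k_b, 4 * w_inh))
                        dly.append(rng.uniform(lo, hi, k_b))
                        inh.append(np.ones(k_b, dtype=bool))
            # delayed self-inhibition: relays driven by the BFC's last pool
            # clamp the whole BFC a couple of milliseconds later, so that
            # self-ignition yields a short burst (a quasi-packet handed to
            # chain 0) instead of tonic saturation
            sc = relays[-cfg.bfc_self_clamp:]
            src = self.bfc_pools[-1][:min(40, cfg.bfc_width)]
            for s in src:
                pre.append(np.full(sc.size, s))
                post.append(sc)
                wgt.append(np.full(sc.size, w_chain))
                dly.append(np.full(sc.size, lo))
                inh.append(np.zeros(sc.size, dtype=bool))
            bfc_all = np.arange(base, base + self.n_bfc)
            for r in sc:
                pre.append(np.full(bfc_all.size, r))
                post.append(bfc_all)
                wgt.append(np.full(bfc_all.size, 8 * w_inh))
                dly.append(np.full(bfc_all.size, 3e-3))
                inh.append(np.ones(bfc_all.size, dtype=bool))

        pre = np.concatenate(pre)
        post = np.concatenate(post)
        order = np.argsort(pre, kind="stable")
        self.syn_post = post[order].astype(np.int64)
        self.syn_weight = np.concatenate(wgt)[order]
        self.syn_delay = np.concatenate(dly)[order]
        self.syn_inh = np.concatenate(inh)[order]
        self.syn_ptr = np.searchsorted(pre[order], np.arange(self.n + 1))
        self.w_chain = w_chain

    def audit(self) -> dict:
        """Structural counts for sanity checks."""
        deg_in = np.bincount(self.syn_post, minlength=self.n)
        return {
            "n_synapses": int(self.syn_post.size),
            "mean_in_degree": float(deg_in.mean()),
            "chain_sizes": [m.shape for m in self.membership],
        }


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Build the network deterministically from a seed."""
    return Network(config, seed=seed)


def scribbler_config(chains: list[ChainSpec] | None = None,
                     n_exc: int = 8000, n_inh: int = 2000,
                     **overrides) -> NetworkConfig:
    """Desk-scale operating point with reliable volley propagation.

    Calibrated for this network size: purely fluctuation-free DC replaced
    by external Poisson drive, and the inhibitory feedback re-tuned so the
    background sits in the asynchronous irregular regime (~5 spikes/s,
    CV(ISI) ~ 0.7) while spike volleys still traverse whole chains.
    """
    if chains is None:
        chains = cycle_chain_specs(3, width=100, radii=[1.0, 0.7, 1.3])
    base = dict(n_exc=n_exc, n_inh=n_inh, chains=chains,
                dc_drive=0.0, nu_ext=11000.0, ext_psp=0.5e-3,
                ipsp_factor=6.0, conn_prob_inh=0.40, stim_rate=1.0)
    base.update(overrides)
    return NetworkConfig(**base)


def ai_background_config(chains: list[ChainSpec] | None = None,
                         n_exc: int = 8000, n_inh: int = 2000,
                         **overrides) -> NetworkConfig:
    """Deeply irregular background preset (CV(ISI) > 0.8).

    Stronger inhibitory fluctuations than ``scribbler_config``; volley
    propagation is stochastic and often fails at this operating point, so
    use it for background-regime studies rather than drawing.
    """
    if chains is None:
        chains = cycle_chain_specs(3, width=100, radii=[1.0, 0.7, 1.3])
    base = dict(n_exc=n_exc, n_inh=n_inh, chains=chains,
                dc_drive=0.0, nu_ext=11000.0, ext_psp=0.5e-3,
                ipsp_factor=7.0, conn_prob_inh=0.45, stim_rate=1.0)
    base.update(overrides)
    return NetworkConfig(**base)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    network: Network,
    duration: float,
    dt: float = 0.1e-3,
    seed: int = 0,
    stimulate: bool = True,
    rate_ceiling: float = 200.0,
    v_init_sd: float = 0.25,
) -> Raster:
    """Clock-driven exact-integration simulation.

    Membrane and synaptic dynamics are advanced with the exact propagator
    of the linear subthreshold system; spikes are thresholded on the grid,
    delays are rounded to the grid, and the refractory period clamps the
    membrane at reset.  Initial membrane potentials are dispersed
    (fraction ``v_init_sd`` of threshold) to avoid artificial synchrony.
    Aborts with diagnostics if the population rate exceeds
    ``rate_ceiling`` (spikes/s per neuron) for more than 100 ms.
    """
    cfg = network.config
    p = cfg.neuron
    rng = np.random.default_rng(seed)
    n = network.n
    n_steps = int(round(duration / dt))
    prop = _propagator(p, dt)
    dc_gain = (1 - np.exp(-dt / p.tau_m)) * p.tau_m / p.capacitance
    dc_term = dc_gain * cfg.dc_drive

    max_delay_steps = int(np.ceil(network.syn_delay.max() / dt)) + 1
    ring = np.zeros((max_delay_steps, n, 2))
    delay_steps = np.maximum(1, np.round(network.syn_delay / dt).astype(int))
    syn_ch = network.syn_inh.astype(int)

    # ignition stimulation: Gaussian pulse packets onto the first pool of
    # chain 0 at the given rate, each spike a chain-strength kick
    stim_kicks: dict[int, float] = {}
    if stimulate and cfg.stim_rate > 0:
        packet_times = np.arange(0.05, duration, 1.0 / cfg.stim_rate)
        for t0 in packet_times:
            for ts in rng.normal(t0, cfg.stim_sigma, cfg.stim_spikes):
                k = int(round(ts / dt))
                if 0 <= k < n_steps:
                    stim_kicks[k] = stim_kicks.get(k, 0.0) + network.w_chain
    stim_targets = network.membership[0][0]

    y1e = np.zeros(n)
    y2e = np.zeros(n)
    y1i = np.zeros(n)
    y2i = np.zeros(n)
    v = rng.normal(0.0, v_init_sd * p.theta, n).clip(-p.theta, 0.95 * p.theta)
    refr = np.zeros(n, dtype=int)
    n_ref = max(1, int(round(p.t_ref / dt)))

    spike_ids: list[np.ndarray] = []
    spike_ts: list[np.ndarray] = []
    ceiling_run = 0
    ceiling_limit = int(0.1 / dt)
    per_step_ceiling = rate_ceiling * n * dt

    ptr, tgt = network.syn_ptr, network.syn_post
    wvec = network.syn_weight
    ring_n2 = n * 2
    flat_ring = ring.reshape(-1)

    w_ext = psc_weight_for_psp(cfg.ext_psp, p.tau_syn_exc, p)
    lam_vec = cfg.nu_ext * dt * network.drive_scale
    lam_ext = float(lam_vec.max())

    for k in range(n_steps):
        slot = k % max_delay_steps
        y1e += ring[slot, :, 0]
        y1i += ring[slot, :, 1]
        ring[slot].fill(0.0)
        if lam_ext > 0:
            y1e += w_ext * rng.poisson(lam_vec)
        if k in stim_kicks:
            y1e[stim_targets] += stim_kicks[k]

        v_new = (prop[4, 0] * y1e + prop[4, 1] * y2e
                 + prop[4, 2] * y1i + prop[4, 3] * y2i
                 + prop[4, 4] * v + dc_term)
        y2e = prop[1, 0] * y1e + prop[1, 1] * y2e
        y1e = prop[0, 0] * y1e
        y2i = prop[3, 2] * y1i + prop[3, 3] * y2i
        y1i = prop[2, 2] * y1i
        v = v_new

        active_ref = refr > 0
        if active_ref.any():
            v[active_ref] = p.v_reset
            refr[active_ref] -= 1

        spiking = np.flatnonzero((v >= p.theta) & ~active_ref)
        if spiking.size:
            v[spiking] = p.v_reset
            refr[spiking] = n_ref
            spike_ids.append(spiking.copy())
            spike_ts.append(np.full(spiking.size, (k + 1) * dt))
            for s in spiking:
                a, b = ptr[s], ptr[s + 1]
                if b > a:
                    idx = ((slot + delay_steps[a:b]) % max_delay_steps
                           ) * ring_n2 + tgt[a:b] * 2 + syn_ch[a:b]
                    np.add.at(flat_ring, idx, wvec[a:b])

            if spiking.size > per_step_ceiling:
                ceiling_run += 1
                if ceiling_run > ceiling_limit:
                    raise RuntimeError(
                        f"population rate exceeded {rate_ceiling}/s per "
                        f"neuron for 100 ms at t={k * dt:.3f}s — the "
                        "network exploded into global synchrony")
            else:
                ceiling_run = 0

    if spike_ids:
        ids = np.concatenate(spike_ids)
        ts = np.concatenate(spike_ts)
    else:
        ids = np.empty(0, dtype=int)
        ts = np.empty(0)
    return Raster(neuron_ids=ids, times=ts, n_neurons=n, duration=duration)


# ---------------------------------------------------------------------------
# Volley and run detection
# ---------------------------------------------------------------------------

def _pool_volleys(raster: Raster, pool: np.ndarray, frac: float,
                  window: float) -> np.ndarray:
    """Times at which at least ``frac`` of a pool fired within ``window``."""
    mask = np.isin(raster.neuron_ids, pool)
    t = np.sort(raster.times[mask])
    need = max(2, int(np.ceil(frac * pool.size)))
    if t.size < need:
        return np.empty(0)
    # sliding count: spikes within [t_i, t_i + window]
    hi = np.searchsorted(t, t + window, side="right")
    starts = np.flatnonzero(hi - np.arange(t.size) >= need)
    if starts.size == 0:
        return np.empty(0)
    # merge overlapping detections into single volleys at the median spike
    volleys = []
    i = 0
    while i < starts.size:
        j = i
        while j + 1 < starts.size and t[starts[j + 1]] - t[starts[j]] < window:
            j += 1
        seg = t[starts[i]:hi[starts[j]]]
        volleys.append(float(np.median(seg)))
        i = j + 1
    return np.asarray(volleys)


def detect_chain_runs(
    raster: Raster,
    network: Network,
    frac: float = 0.5,
    window: float = 3e-3,
    max_pool_gap: float = 15e-3,
) -> list[dict]:
    """Detect volley runs along each chain.

    A volley is at least ``frac`` of a pool firing within ``window``;
    volleys of consecutive pools separated by less than ``max_pool_gap``
    are assembled into runs.  A run is complete when it spans every pool.
    """
    runs = []
    for ci, pools in enumerate(network.membership):
        vol = [_pool_volleys(raster, pools[k], frac, window)
               for k in range(pools.shape[0])]
        used = [np.zeros(v.size, dtype=bool) for v in vol]
        for s0 in range(vol[0].size):
            t0 = vol[0][s0]
            if used[0][s0]:
                continue
            used[0][s0] = True
            times = [t0]
            for k in range(1, len(vol)):
                cand = np.flatnonzero(
                    (vol[k] > times[-1]) &
                    (vol[k] <= times[-1] + max_pool_gap) & ~used[k])
                if cand.size == 0:
                    break
                used[k][cand[0]] = True
                times.append(vol[k][cand[0]])
            runs.append({
                "chain": ci,
                "pool_times": np.asarray(times),
                "complete": len(times) == len(vol),
                "last_pool": len(times) - 1,
            })
    runs.sort(key=lambda r: r["pool_times"][0])
    return runs


def run_sequences(runs: list[dict], network: Network,
                  max_gap: float = 0.05) -> list[int]:
    """Lengths of uninterrupted run sequences.

    Complete runs followed (within ``max_gap`` of their last volley) by a
    complete run of a successor chain are chained together; the sequence
    length is the number of *additional* chains traversed after the first
    (so a lone run has length 0, matching a geometric count of successes
    before the first failure).
    """
    complete = [r for r in runs if r["complete"]]
    complete.sort(key=lambda r: r["pool_times"][0])
    used = [False] * len(complete)
    lengths = []
    for i, r in enumerate(complete):
        if used[i]:
            continue
        used[i] = True
        count = 0
        cur = r
        while True:
            succ = network.config.chains[cur["chain"]].successors
            t_end = cur["pool_times"][-1]
            nxt = None
            for j, q in enumerate(complete):
                if used[j] or q["chain"] not in succ:
                    continue
                dt0 = q["pool_times"][0] - t_end
                if -0.005 < dt0 < max_gap:
                    nxt = j
                    break
            if nxt is None:
                break
            used[nxt] = True
            cur = complete[nxt]
            count += 1
        lengths.append(count)
    return lengths


# ---------------------------------------------------------------------------
# Population decoding
# ---------------------------------------------------------------------------

def decode_trajectory(
    raster: Raster,
    network: Network,
    bin_width: float = 1e-3,
    weight: float = 0.02,
    smooth: float = 2e-3,
    threshold_frac: float = 0.1,
    normalize: bool = True,
) -> DecodedTrajectory:
    """Population decoding of the raster into a movement.

    Pool activities are binned at ``bin_width``, smoothed, weighted by
    ``weight`` (seconds) and summed against the pools' preferred
    velocities.  With ``normalize=True`` (default) the velocity is the
    activity-weighted mean of the preferred velocities — a normalized
    population vector — whenever total pool activity exceeds
    ``threshold_frac`` of a full volley; below that the decoded velocity
    is zero (pen at rest).  Position integrates velocity from the origin.
    """
    n_bins = int(np.ceil(raster.duration / bin_width))
    t = (np.arange(n_bins) + 0.5) * bin_width
    num = np.zeros((n_bins, 2))
    den = np.zeros(n_bins)
    act_by_chain = np.zeros((len(network.membership), n_bins))
    sigma_bins = smooth / bin_width

    for ci, pools in enumerate(network.membership):
        pv = network.pool_velocities[ci]
        for k in range(pools.shape[0]):
            mask = np.isin(raster.neuron_ids, pools[k])
            counts = np.bincount(
                np.minimum((raster.times[mask] / bin_width).astype(int),
                           n_bins - 1), minlength=n_bins).astype(float)
            if sigma_bins > 0:
                counts = gaussian_filter1d(counts, sigma_bins)
            a = weight * counts
            num += a[:, None] * pv[k]
            den += a
            act_by_chain[ci] += counts

    active_chain = np.where(act_by_chain.max(axis=0) > 0,
                            act_by_chain.argmax(axis=0), -1)
    if normalize:
        w0 = network.config.chains[0].width
        floor = weight * threshold_frac * w0
        v = np.where(den[:, None] > floor, num / np.maximum(den, 1e-300)[:, None],
                     0.0)
        active_chain = np.where(den > floor, active_chain, -1)
    else:
        v = num
    pos = np.zeros_like(v)
    pos[1:] = np.cumsum(0.5 * (v[1:] + v[:-1]) * bin_width, axis=0)
    return DecodedTrajectory(t=t, v=v, position=pos,
                             active_chain=active_chain)


# ---------------------------------------------------------------------------
# Run-length statistics
# ---------------------------------------------------------------------------

def run_length_stats(lengths: list[int] | np.ndarray,
                     alpha: float = 0.01) -> dict:
    """Maximum-likelihood geometric fit to run-sequence lengths.

    For P(n) = p0 (1 - p0)^n, n = 0, 1, 2, ..., the MLE is
    p0 = 1 / (1 + mean).  Goodness of fit by chi-square with tail bins
    pooled to an expected count of at least 5.
    """
    n = np.asarray(lengths, dtype=int)
    if n.size < 30:
        raise ValueError("need at least 30 sequences")
    if np.all(n == 0):
        return {"p0": 1.0, "chi2": 0.0, "dof": 0, "p_value": 1.0,
                "reject": False, "n": int(n.size)}
    p0 = 1.0 / (1.0 + n.mean())
    kmax = int(n.max())
    obs = np.bincount(n, minlength=kmax + 1).astype(float)
    probs = p0 * (1 - p0) ** np.arange(kmax + 1)
    probs[-1] = (1 - p0) ** kmax  # tail mass folded into the last cell
    exp = probs * n.size
    # pool cells from the tail until every expected count is >= 5
    o, e = [], []
    acc_o = acc_e = 0.0
    for k in range(kmax + 1):
        acc_o += obs[k]
        acc_e += exp[k]
        if acc_e >= 5:
            o.append(acc_o)
            e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and e:
        o[-1] += acc_o
        e[-1] += acc_e
    o, e = np.asarray(o), np.asarray(e)
    dof = max(1, o.size - 1 - 1)  # cells - 1 - one fitted parameter
    stat = float(np.sum((o - e) ** 2 / e)) if o.size > 1 else 0.0
    p_val = float(chi2.sf(stat, dof)) if o.size > 1 else 1.0
    return {"p0": float(p0), "chi2": stat, "dof": dof, "p_value": p_val,
            "reject": bool(p_val < alpha), "n": int(n.size)}
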