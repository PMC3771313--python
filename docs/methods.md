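# Methods

Models, parameters and numerical choices behind each `scribblekit`
module. Units throughout: seconds, millimetres, volts, amperes, hertz.

## Kinematics (`scribblekit.kinematics`)

**Differentiation.** `differentiate` computes velocity and acceleration
with a Savitzky–Golay filter (`smooth_window=11` samples, `polyorder=3`)
rather than raw finite differences: drawing trajectories are sampled at
~100 Hz and the power law involves ratios of derivatives, so unsmoothed
differencing amplifies quantization noise into the curvature estimate.
Window and order were fixed a priori to preserve cubic (hence parabolic)
segments exactly.

**Two-thirds power law.** `power_law_fit` regresses `log v` on
`log κ` (ordinary least squares), reporting the exponent `β`, gain `K`
and `r²`. Samples with speed below `V_FLOOR = 1 mm/s` or curvature
below `C_FLOOR = 1e-4 mm⁻¹` are excluded — both logs diverge at rest
points and on straight segments, and those samples carry no information
about the law. An optional boolean `mask` restricts the fit (used to
pool only the samples where a decoded network is actively drawing).

**Equi-affine quantities.** Equi-affine speed is
`σ̇ = (ẋÿ − ẏẍ)^{1/3}`; equi-affine curvature is computed from
derivatives with respect to equi-affine arclength. Parabolas are
exactly the curves of zero equi-affine curvature, and `β = 2/3` is
equivalent to constant `σ̇`. `equi_affine_transform` applies a full
affine map and rescales time so the determinant-1 (equi-affine) part is
what the invariance tests exercise. Near inflection points `σ̇ → 0`
and the curvature estimate is undefined; such samples are returned as
non-finite and callers drop them (the acceptance checks trim 10 edge
samples where the filter pads).

## Parabola segmentation and fitting (`scribblekit.parabolas`)

**Segmentation.** `segment_activity` splits rest from movement at
`v_rest = 10 mm/s` (minimum duration 0.25 s); `segment_strokes_curvature`
then cuts movement epochs at local maxima of Euclidean curvature —
stroke boundaries are where the pen turns most sharply.

**Parabola fit.** `fit_parabola` searches over the parabola's axis
orientation `θ`; in the rotated frame it solves a linear least-squares
quadratic and reports the residual as the dimensionless criterion
`D = RSS / (n · diag²)` where `diag` is the stroke's bounding-box
diagonal, so `D` is comparable across stroke sizes. The reported
parameter `p` is the latus-rectum-style coefficient of `v² = 4a·u`
(`p = 2a` of the internal parametrization). Strokes that are straight
to numerical precision (degenerate quadratic) raise `ValueError` rather
than returning an arbitrary orientation.

**Model selection.** `model_selection_sic` compares parabola,
higher-order polynomial and ellipse fits with a Schwarz-style penalized
likelihood, so a parabola is preferred only when extra parameters don't
buy enough residual.

**Clustering.** `cluster_parabolas` clusters fits in the feature space
`(cos θ, sin θ, log p)` — orientation enters through its embedding on
the circle to avoid the wrap-around discontinuity, and `p` through its
log because the parameter is scale-like. Requires ≥ 10 fits; outlier
bins are labelled `-1` in `ParabolaClusterModel.assignments`.

## Spike-train hidden Markov model (`scribblekit.spikehmm`)

Spikes are binned (`bin_spikes`, `dt = 50 ms`) into per-unit Poisson
counts. `mll_changepoints` scans a short history (0.2 s) for jumps in
the multi-unit log likelihood and returns candidate state-boundary
times; `init_hmm` pools the inter-changepoint segments (requiring at
least as many segments as states) into initial firing-rate vectors.
`baum_welch` then runs EM with log-domain forward–backward (`max_iter
= 500`, relative log-likelihood tolerance for convergence); a small
rate floor keeps emissions finite for silent units. `viterbi_path`
decodes the maximum-probability state sequence and `match_states`
resolves label permutation against a reference rate matrix via the
Hungarian assignment. `dominant_states` extracts contiguous periods
where one state's posterior exceeds `p_min = 0.5` for at least 0.1 s,
and `align_states_to_movement` relates those periods to movement
direction.

## Tuning analysis (`scribblekit.tuning`)

`rate_estimate` turns a spike train into a smoothed rate series (10 ms
bins, Gaussian kernel). `delay_regression_pva` regresses rate on
position, velocity and acceleration over a grid of sensorimotor delays
(±200 ms); predictions are clipped at zero because a linear model can
otherwise predict negative rates, which mildly biases `r²` for units
near their baseline. `partial_contribution` measures each kinematic
group's unique contribution (increase in residual when the group is
dropped) across the delay grid, and `dominant_stripe` asks whether the
contribution map is dominated by a single delay stripe — the stripe's
lag is the estimated sensorimotor delay. Note `dominant_stripe`'s
criterion (more than half the row above half the row maximum) returns
`True` for a uniform map; callers should check effect size separately.
`speed_model_fit` compares Euclidean-speed and equi-affine-speed
regressors at their best lags and assesses the winner with a
permutation test (circular shifts of the rate series, preserving
autocorrelation) rather than parametric tests.

## Precise-timing analysis (`scribblekit.timing`)

**Search space.** `enumerate_components` counts ordered unit pairs on
distinct electrodes (same-electrode pairs are excluded because spike
sorting cannot rule out cross-talk) and multiplies by drawing
components and interval bins to size the hypothesis space.
`relation_surprise` converts a support count into bits via the normal
tail probability of the surrogate distribution
(`normal_tail_probability`), i.e. `−log₂ p`.

**Counting.** `count_support` counts, for each interval bin
(presets: `INTERVAL_BINS_WIDE`/`INTERVAL_BINS_NARROW`, 50 bins with
deliberate gaps between them so a bin is a sharp hypothesis), the
occurrences of a fixed unit-to-unit latency inside a time window
anchored to a drawing component. Planted latencies should sit mid-bin:
a latency exactly on a bin edge is split between bin and gap by float
rounding.

**Teetering surrogates.** `teeter(data, w)` jitters every spike
uniformly within `±w/2` while preserving per-unit counts and the
refractory floor. Precision at scale finer than `w` is destroyed;
slower structure (rates, tuning, bursts) is preserved. The
significance of observed support is the rank of the real relations
score among `n_outer` teetered surrogates, with the score itself
computed from `n_inner` inner surrogates (`relations_score` sums the
top deduplicated relation surprises). `significance_scan` repeats this
at several teetering widths `W`: real millisecond precision is
significant for `W` at and above the planted jitter scale and vanishes
when `W` shrinks below it, whereas rate artifacts are significant at
every `W`. A noise threshold (default minimum support 20) suppresses
pure-chance relations.

## Synfire scribbler network (`scribblekit.synfire`)

**Neurons and synapses.** Leaky integrate-and-fire neurons
(`tau_m = 20 ms`, threshold 20 mV above rest, refractory 2 ms,
capacitance 250 pF) with alpha-current synapses (rise 0.2 ms exc /
0.6 ms inh), integrated exactly per time step with the matrix
propagator of the linear subthreshold dynamics (`dt = 0.1 ms`);
`psc_weight_for_psp` converts a desired PSP amplitude into the
corresponding current amplitude analytically.

**Architecture.** Three synfire chains of 20 pools × 100 neurons,
embedded in 8000 excitatory + 2000 inhibitory background neurons.
Each chain encodes one parabolic stroke: pool `k` carries a velocity
label interpolated from `v_start` to `v_end`, so a volley traversing
the chain "draws" the stroke (`decode_trajectory` integrates the
population-labelled velocity with a 8 ms smoothing kernel). The last
pool connects to its successors' first pools with dilution
`p_ce = 0.75`, making chain-to-chain continuation stochastic by
design: `run_sequences` / `run_length_stats` test the resulting
uninterrupted-sequence lengths against a geometric law
(chi-squared GoF, `alpha = 0.01`, ≥ 30 sequences required).

**Background regime.** `scribbler_config` replaces DC drive with
per-neuron external Poisson input (`nu_ext = 11 kHz` of 0.05 mV EPSPs)
and inhibitory feedback (`ipsp_factor = 6`, I connection probability
0.40), placing the background in an asynchronous-irregular regime
(~5 spikes/s, CV(ISI) ≈ 0.7) through which volleys still propagate.
`ai_background_config` is a more irregular preset where propagation
often fails — for background studies, not drawing.

**Self-re-ignition (BFC).** A backward-and-forward-connected group
(100 × 10) is clamped by global-inhibition relays (`k_g = 6` per pool,
`k_b = 1000` synapses each) while any chain is active; when activity
lapses, the disinhibited BFC self-ignites (drive multiplier 1.1,
shaped into a burst by `bfc_self_clamp = 20` delayed self-inhibition
relays) and restarts chain 0. The wiring constants are not derivable
from first principles; they were chosen by `scripts/synfire_sweep.py`,
which scores grid points on (a) switching reliability — the fraction of
activity lapses answered by a complete chain-0 restart within 1 s
(target ≥ 0.9) — and (b) spontaneous ignition — complete runs starting
with no predecessor-chain activity in the prior 150 ms (target < 1%).
Predecessor activity is detected with a sensitive volley threshold
(`frac = 0.25` of a pool firing within the volley window) because
weakened but complete traversals are invisible at the default
`frac = 0.5` and would otherwise be misread as spontaneous events.

## Movement syntax (`scribblekit.syntax`)

`parse_strokelets` cuts a trajectory at sign changes of the
acceleration component along the movement (so consecutive strokelets
alternate accelerating/decelerating); `describe` summarizes each with
a 10-dimensional descriptor (direction embedding, log duration/extent,
curvature and speed shape). `group_strokelets` k-means-clusters the
descriptors, selecting `k` within `k_range` by silhouette unless the
range is pinned. `transition_model` builds the group-to-group
transition count matrix, and `ib_cluster` compresses it with
agglomerative information bottleneck: groups are merged greedily by
minimum mutual-information loss down to `n_clusters`, reporting the
fraction of predictive information retained. `extract_cycles` reads
words off the cluster-level transition graph as its strongly-recurrent
cycles, with gateway transitions connecting words.

## Synthetic data (`scribblekit.synthgen`)

Generators produce data with exact ground truth:

* `gen_parabolic_scribble` concatenates parabolic strokes from a cyclic
  velocity specification (`velocity_cycle_spec`: 3 stroke classes,
  ~300 mm/s, optional waypoint jitter), returning per-segment truth
  (parabola parameter, orientation, class, times).
* `gen_tuned_spike_trains` draws inhomogeneous-Poisson spikes whose
  rate is a baseline plus delayed linear terms in velocity and/or
  equi-affine speed.
* `gen_markov_spike_trains` simulates a continuous-time Markov chain
  over hidden states with per-state, per-unit Poisson rates.
* `gen_poisson_trains` / `embed_precise_patterns` produce background
  Poisson activity and plant millisecond-precise unit-to-unit spike
  pairs (Gaussian jitter) anchored to drawing-component occurrences,
  returning a ledger of every planted spike.
* `gen_syntax_trajectory` emits a stroke sequence from a 3-word cyclic
  grammar with per-stroke word/group truth.

**What the synthetic data emulates** — the statistical structure the
analyses target: parabolic stroke geometry and the two-thirds law,
rate tuning at a fixed sensorimotor delay, discrete firing-rate
states, precise timing against a jittered background, and cyclic
stroke grammars. **What it does not emulate** — real recordings'
non-Poisson interval statistics (bursting, adaptation), electrode
cross-talk and sorting errors, slow nonstationarity of rates, muscle
and biomechanical filtering of the trajectory, or correlated noise
across units. Conclusions about method validity transfer; absolute
detection thresholds on real data will differ.

## Numerical and reproducibility choices

* All stochastic functions take an explicit integer seed and use
  `numpy.random.default_rng`; nothing touches the global RNG state.
* CSV writers emit `repr` of each float and readers parse with
  `float_precision="round_trip"`, so every artifact round-trips
  exactly. Readers validate columns, NaNs, sampling uniformity and
  refractory violations, reporting offending rows.
* Every pipeline output is stamped with the package version and a
  SHA-256 hash of the canonical run configuration.
* The network simulator uses exact subthreshold propagators at
  `dt = 0.1 ms`; results are deterministic given (build seed,
  simulation seed).

## Limitations

* The tuning-lag estimate is quantized by the delay grid (10 ms) and,
  for equi-affine-speed units, further blurred because `σ̇` is
  piecewise-constant within each parabolic stroke — lags are recovered
  to ~±50 ms for `σ̇`-tuned units versus ±10 ms for velocity-tuned ones.
* `delay_regression_pva` clips negative rate predictions, slightly
  biasing `r²` near baseline; `partial_contribution` is the more
  reliable lag estimator because it isolates each regressor group.
* The agglomerative information bottleneck is greedy and can oversplit
  when transition rows are nearly but not exactly identical; exact
  block recovery is only guaranteed for exactly block-structured
  matrices.
* `detect_chain_runs` classifies volleys by the fraction of a pool
  firing within a window; near the propagation margin the default
  threshold (`frac = 0.5`) fragments weakened runs. Analyses that need
  completeness (e.g. predecessor attribution in the calibration sweep)
  should use `frac = 0.25`.
* Geometric run-length statistics need ≥ 30 complete sequences; short
  simulations (≲ 15 s at the default operating point) do not reach
  that.
* Equi-affine curvature is undefined at inflections and is returned as
  non-finite there; downstream code must mask such samples.
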