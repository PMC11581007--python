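# Methods

This note documents the models, algorithms and numerical choices behind
`tunespace`, and what its synthetic-data validation does and does not
establish.

## Encoding models

**Stimulus representation.** Sounds are represented as a 32-channel
log-compressed gammatone spectrogram `s(f, t)` sampled at 100 Hz
(10-ms frames), channels log-spaced from 200 Hz to 20 kHz (≈1/6 octave
per channel). Each gammatone channel is a cascade of two complex
one-pole resonators at the channel center frequency with bandwidth
1.019·ERB(f); the envelope is the magnitude of the complex output,
averaged over non-overlapping 10-ms frames and compressed as
`log(x + ε)` with floor `ε = 1e-4` of full scale (so digital silence maps
to a finite constant). The ERB formula is a configurable affine law in
frequency, defaulting to the standard human form
ERB(f) = 24.7·(4.37·f/1000 + 1); the species-specific alternative can be
supplied as coefficients.

**LN model.** A shared bank of M rank-1 FIR filters
`h_m(f, u) = φ_m(f)·τ_m(u)` (defaults M = 100, F = 32 channels, U = 25
lags = 250 ms) is convolved causally with the spectrogram; per-neuron
weights `w_im` mix the M filter outputs into a linear drive, followed by
a per-neuron double-exponential (Gompertz) output nonlinearity

    r = b + a·exp(−exp(−k·(x − s)))

with baseline `b`, amplitude `a` (saturation `b + a`), threshold `s` and
gain `k`; the nonlinearity is monotone increasing for `k > 0`. The
rank-1 filters are stored as profile pairs and only materialized on
request.

**Population CNN.** Four layers sharing the first three across neurons:
two causal 1-D convolution layers (full-scale widths 80 filters × 32
channels × 15 taps, then 100 × 80 × 10), two dense per-frame layers
(100 × 100, then 100 × N for N neurons), ReLU between layers, and the
same per-neuron double-exponential output. Causality is implemented by
zero left-padding; the architecture's temporal footprint is
`conv1_taps + conv2_taps − 1` = 24 frames at full scale, so the default
dSTRF lag window of 25 frames always contains it. Conv layers carry
bias terms.

All forward passes, analytic backpropagation gradients, input Jacobians
and the Adam optimizer are implemented directly in numpy; the models
are small enough (≤ a few 10⁵ parameters) that this is both fast and
exactly reproducible. Gradients are verified against central finite
differences in the test suite.

## Fitting protocol

Stimulus and response channels are min-max normalized to [0, 1] using
fit-data statistics only (a constant channel maps to zeros; the affine
maps are stored and reused on validation data). Optimization is
full-batch Adam on the MSE over all neurons simultaneously, plus an L2
penalty (default 1e-4 in normalized units) on linear weights only —
never on output-nonlinearity parameters.

Fitting is two-stage: a coarse stage with the output nonlinearity
replaced by a per-neuron level shift (learning rate 0.01, stop
tolerance 1e-3), then the double-exponential is restored and training
continues at learning rate 0.001, tolerance 1e-4. The stop rule halts a
stage when the best validation loss (computed on the fold's excluded
bins) improves by less than the stage tolerance, in relative terms,
over the trailing 50 epochs; a 50-epoch minimum guards against the
transient right after a stage switch, during which full-batch Adam can
stall for tens of epochs before resuming descent. When the
double-exponential is restored, `b` and `a` are set from the response
mean and range and `(s, k)` are centered and scaled to the stage-1
drive distribution, with the gain capped at `k ≤ 8` — starting the
sigmoid in its sensitive range rather than saturated. Without the cap,
sparse responses (low-variance drives) start the sigmoid fully
saturated and stage 2 stalls in a vanishing-gradient plateau; with it,
the same fits converge several hundred epochs sooner and sparse
(gain-control-like) neurons fit at all. The L2 default suits noisy
data; fits to noiseless synthetic responses use much smaller penalties
(1e-5 to 1e-7), since regularization strength should match the noise
level.

Jackknifing: the fit period is partitioned into `n_jackknife` contiguous
temporal blocks (contiguity respects temporal correlation; interleaved
bins would leak information across the fit/validation boundary). Each
fold excludes one block (12.5% at the 8-fold default), runs `n_inits`
seeded random initializations through both stages, and retains the
initialization with the lowest MSE on the excluded block. Every random
draw derives from the single fit seed through named substreams, so
refits are bit-reproducible (predictions agree to ≤1e-6).

## dSTRF and tuning subspace

The dynamic STRF at frame `t` is the Jacobian `∂r_i(t)/∂s(f, t−u)`,
`u ∈ [0, 25)`, evaluated at the actual stimulus — computed by
back-propagating a unit seed from output `(i, t)` through the network,
batched over frames. For the LN model this reduces analytically to the
static effective filter scaled by the time-varying slope of the output
nonlinearity, and a central-finite-difference oracle is used in tests to
validate the CNN path (agreement ≤1e-3 max relative error at step 1e-3,
with the O(step²) Richardson behavior).

Per-neuron dSTRFs are computed for each jackknife member and combined
coefficient-wise by the shrinkage average `m·max(0, 1 − (se/|m|)²)`
(mean `m`, standard error `se` across members). This is the simplest
variance-penalized shrinkage consistent with attenuating noisy
coefficients; it never flips a sign and never increases a magnitude,
and is exposed as a strategy option. By default dSTRFs are returned in
physical units — the Jacobian is chain-ruled through the stored
normalization maps (`d r_raw / d s_raw = scale_r / scale_s(f) ·
d r_norm / d s_norm`) — so filters are comparable across models and to
ground truth.

The tuning subspace is the uncentered PCA (SVD of the T × (F·U) stack,
no mean subtraction) of the dSTRF collection: uncentered so the
subspace contains the mean dSTRF, which carries the LN-like component
needed for prediction; centered PCA is available as an option. The
dimensionality N is the smallest count whose cumulative explained
variance reaches the threshold (default 90%, inclusive). Component
signs are fixed by making each filter's largest-magnitude coefficient
positive; all downstream metrics (SSI via |cc|, TSI from data-binned
marginals) are invariant to that arbitrary choice.

Projections `x_j(t) = Σ_f Σ_u g_j(f,u)·s(f, t−u)` use the same causal
zero-padded convolution as the models. The subspace readout is a
two-layer dense network (default widths 30 and 20, ReLU, double-
exponential output) fit from projections to rate under the same
protocol; the hidden widths are a package choice — only "two-layer" is
constrained by the model family. Poly-1/Poly-2 readouts are linear in
their parameters and are fit in closed form by ridge least squares
(penalty = the configured L2 strength; intercept unpenalized), which
reaches the same optimum as gradient descent deterministically.

## Tuning metrics

* **Tuning surfaces / marginal curves** — binned means of the (actual
  or predicted — both supported, the choice is the caller's) rate over
  projections; 2-D surfaces default to 25 × 25 bins spanning the central
  99% of each projection, bins with fewer than 5 samples are flagged
  empty and excluded from maxima. Marginal (TSI) curves use 20 bins.
* **TSI** — from adjacent-bin derivatives `y'`:
  `1 − |Σy'|/Σ|y'|` if the summed derivative above 0 exceeds that below,
  else `−1 + |Σy'|/Σ|y'|`; +1 upward-symmetric, −1 downward-symmetric,
  0 monotone. A tie in the branch condition resolves to the positive
  branch; at a tie both branches agree wherever the curve is monotone.
  Flat curves return NaN with a warning.
* **SSI** — `Σ_{m,n} |cc(g_a,m, g_b,n)| / min(M, N)` over the 4 largest
  filters by default (an option selects the 80%-variance set instead).
  Absolute correlations are used because PCA filter signs are
  arbitrary; signed correlations would make the index depend on that
  convention and break its [0, 1] anchoring.
* **Noise-corrected prediction correlation** — CC_norm of Schoppe et
  al. (2016): Pearson correlation of prediction with the trial-mean
  PSTH divided by the square root of the signal-power fraction
  estimated from trial-to-trial covariance,
  `SP = (var(Σ_trials) − Σ_trials var)/(n(n−1))`. It reduces exactly to
  plain Pearson when all trials are identical; the uncorrected variant
  is also exposed (pass the PSTH directly to `signal_correlation`).
* **Modulation power spectrum** — squared magnitude of the 2-D FFT of a
  filter over (log-frequency, lag), axes in Hz and cycles/octave.
* **Response-field tiling** — per-neuron masks where a site-level
  tuning surface exceeds 80% of its occupied maximum; overlap counted
  per grid cell; the shuffle control applies seeded random toroidal
  translations, which preserve each field's shape and area exactly.
* **Spike-width classes** — narrow iff width < threshold (0.35 ms /
  0.375 ms depending on probe type); a width exactly at threshold is
  regular.

## Synthetic ground truth

The generator emulates the statistics the pipeline consumes, not raw
audio: 32-channel spectrogram-like stimuli (smoothed Gaussian noise,
ripple mixtures with stated modulation content, or block sequences with
heterogeneous smoothness and a ±10 dB level rove emulating the
natural-segment design), plus neurons with known filters and
combination rules:

* linear: `r = dexp(x₁)`;
* energy: `r = dexp(√(x₁² + x₂²))` on an exact quadrature (90°-shifted
  complex Gabor) pair — phase-invariant by construction;
* gain control: `r = dexp(x₁)·exp(−β·x₂²)`, suppression strength β = 4
  in unit-RMS projection units;
* and-gate: `r = dexp(min(x₁, x₂))`.

Projections are scaled by a single joint RMS over the neuron's
dimensions (no per-dimension centering), which preserves the rotation
symmetry that makes energy responses exactly phase-invariant; quadrature
pairs are likewise normalized by one joint scale rather than
per-filter. Rates are `rate_scale` (default 50 spikes/s) times the
rule output; trial rasters are Poisson counts at the 10-ms frame scale
(a Gaussian option exists for high-rate regimes).

What this does *not* emulate: natural-sound higher-order correlations,
adaptation and other history dependence, non-Poisson spiking, across-
neuron noise correlations, and recording artifacts. Passing the
recovery tests therefore demonstrates that the pipeline's machinery is
correct and self-consistent — not that real cortical data would yield
equally clean subspaces.

## Desk-scale problem sizes

The validation suite runs everything at sizes a laptop CPU handles in
minutes, chosen once as the package's reference conditions:

* LN self-consistency: 2-minute fit stimulus (12,000 frames) + 12-s
  validation, M = 30 filters, 2 jackknife folds × 2 inits.
* CNN full loop (energy / gain-control recovery, functional
  equivalence): 60-s fit stimulus (6,000 frames), reduced widths
  (conv1 20 × 32 × 12, conv2 24 × 20 × 8, dense 24), 8 jackknife
  folds × 2 inits, dSTRFs at stride 2. Between-model equivalence
  correlations are measured on a fresh 30-s stimulus never seen by any
  fit — short windows estimate a between-model correlation with
  sampling error of a few hundredths, which would be measurement noise,
  not model quality.

The full-scale defaults (M = 100; 80/100/100 CNN widths; 8 folds ×
5 inits) remain the package defaults for real datasets.

## Known limitations

* The exact shrinkage function of the original dSTRF averaging and the
  exact noise-ceiling normalization are not pinned down by the model
  family this package follows; the implemented choices are documented
  above and exposed as options.
* Full-batch Adam is deterministic but slow for long stimuli; there is
  no minibatching or GPU path.
* The gain-control rule at β = 4 produces very sparse responses that
  small CNNs fit only partially; the suppressive-dimension TSI is still
  recovered, but prediction correlations for such neurons are modest at
  desk scale.
* `filter_segment_pool` holds candidate excitation patterns in memory;
  corpus-scale (10⁵–10⁶ segment) selection would need a streaming
  refactor.
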