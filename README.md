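# tunespace

Tuning-subspace analysis of neural-network encoding models for auditory
cortex.

## The problem

Convolutional neural networks predict the time-varying firing of
auditory cortical neurons in response to natural sounds far better than
the classical linear-nonlinear spectro-temporal receptive field (LN
STRF) — but a fitted CNN is hard to interpret. `tunespace` implements a
pipeline that *flattens* a CNN into an interpretable multi-filter
(subspace) model:

1. **Fit** an encoding model — an LN model or a population CNN — from a
   log-gammatone spectrogram `s(f, t)` to per-neuron firing rates
   `r_i(t)` at 100 Hz, with the standard protocol (min-max
   normalization, two-stage Adam schedule, 8-fold jackknife, best of 5
   random initializations, L2 on linear weights).
2. **Differentiate**: at every stimulus frame compute the dynamic STRF
   (dSTRF), the locally linear filter
   `d_t(f, u) = ∂r_i(t)/∂s(f, t−u)` — the Jacobian of the model output,
   shrinkage-averaged across jackknife members.
3. **Reduce**: PCA over the dSTRF collection yields a small set of
   orthonormal filters `g_j(f, u)` (typically a handful reach 90% of
   dSTRF variance) — the neuron's *tuning subspace*.
4. **Refit**: project the stimulus into the subspace,
   `x_j(t) = Σ_{f,u} g_j(f,u)·s(f, t−u)`, and fit a compact readout
   `r(t) = F(x_1…x_N)` — a small dense network, or first/second-order
   polynomials for comparison with spike-triggered-covariance-style
   models.
5. **Quantify** tuning: tuning surfaces and marginal curves over the
   projections; the tuning symmetry index
   `TSI = ±(1 − |Σy'|/Σ|y'|)` (+1 upward-symmetric, −1
   downward-symmetric, 0 monotone); the subspace similarity index
   `SSI = Σ|cc(g_a,m, g_b,n)|/min(M,N)` between neurons; modulation
   power spectra of filters; response-field tiling across a local
   population with a shuffle control; noise-corrected prediction
   correlations.

Everything is validated on synthetic populations with known ground
truth (linear, quadrature-energy, gain-control and and-gate neurons),
so each stage's recovery properties are measurable.

The package also includes the stimulus-construction toolkit used for
this kind of experiment: gammatone spectrogram frontend,
excitation-pattern-based diversity selection of natural-sound segments,
and crossfaded sequence assembly with level roving.

## Worked example

```python
import numpy as np
from tunespace import (FitConfig, PopulationCNN, ensemble_dstrf,
                       fit_population_model, generate_stimulus,
                       pca_subspace, project_stimulus, signal_correlation,
                       simulate_population, subspace_recovery_error,
                       tuning_curve, tuning_symmetry_index)
from tunespace.synthetic import GroundTruthNeuron, gabor_filter, quadrature_pair

# A small population with known ground truth: a linear (LN-like) neuron, a
# phase-invariant "energy" neuron (quadrature Gabor pair,
# r = dexp(sqrt(x1^2 + x2^2))), and a gain-control neuron whose second
# filter suppresses the response.
stim = generate_stimulus("smoothed_noise", {"n_frames": 6800}, seed=21)
pop = [
    GroundTruthNeuron("linear",
                      gabor_filter(32, 25, f0=0.35, u0=0.25, omega_u=0.10)[None]),
    GroundTruthNeuron("energy",
                      quadrature_pair(f0=0.55, u0=0.3, omega_u=0.12, sigma_u=3.0)),
    GroundTruthNeuron("gain_control", np.stack([
        gabor_filter(32, 25, f0=0.4, u0=0.2, omega_u=0.10),
        gabor_filter(32, 25, f0=0.7, u0=0.3, omega_f=0.08, omega_u=0.0)])),
]
data = simulate_population(pop, stim, n_trials=10, seed=22)

cnn = PopulationCNN(n_neurons=3, conv1_filters=20, conv1_lags=12,
                    conv2_filters=24, conv2_lags=8, dense_width=24)
cfg = FitConfig(n_jackknife=8, n_inits=2, seed=1, max_epochs=3000,
                l2_strength=1e-5)
ens = fit_population_model(cnn, stim.slice_time(0, 6000),
                           data.true_rates[:, :6000], cfg)

pred = ens.predict(stim.slice_time(6000, 6800))
for i, n in enumerate(pop):
    r = signal_correlation(pred[i], data.true_rates[i, 6000:])
    print(f"{n.kind:>12}  held-out r = {r:.3f}")

# dSTRF -> PCA subspace for the energy neuron; check the quadrature plane
stack = ensemble_dstrf(ens, stim.slice_time(0, 6000), neuron=1, stride=2)
sub = pca_subspace(stack, var_threshold=0.90)
angles = subspace_recovery_error(pop[1].filters, sub.filters[:2])
proj = project_stimulus(sub, stim.slice_time(0, 6000))
tsi = [tuning_symmetry_index(tuning_curve(proj.x[j], data.true_rates[1, :6000]))
       for j in range(2)]
print("energy subspace: N =", sub.n_components,
      " plane recovery (deg):", np.round(angles, 1),
      " marginal TSI:", np.round(tsi, 2))
```

Output from this exact script (≈12 min on one CPU):

```
      linear  held-out r = 0.991
      energy  held-out r = 0.985
gain_control  held-out r = 0.928
energy subspace: N = 2  plane recovery (deg): [8.7 9.3]  marginal TSI: [0.99 0.97]
```

The fitted population CNN predicts each neuron's held-out response
(r = 0.93–0.99). For the energy neuron, two principal components of the
dSTRF collection reach the 90% variance threshold and span the true
quadrature plane to within ~9°; both marginal tuning curves are
strongly upward-symmetric (TSI near +1) — the signature of a
phase-invariant energy computation, which an LN model cannot express
(its tuning curve is monotone, TSI near 0). Fitting the single-neuron
variants of this example is noticeably harder than the population fit:
the shared convolutional layers benefit from the linear neuron's
gradient signal, which is precisely the motivation for population
encoding models.

A full pipeline (simulate → fit → dstrf → subspace → readout → metrics)
with HDF5/TSV/JSON outputs is available as a library call
(`tunespace.pipeline.run_pipeline`) or from the shell:

```sh
tunespace run --config run.yaml --seed 1234 --out results/
```

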