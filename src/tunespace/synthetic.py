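"""Ground-truth stimuli and neural populations with known tuning subspaces.

Every pipeline stage (fitting, dSTRF extraction, PCA, readout fitting,
metrics) is testable against populations whose responses are generated
by known multi-filter rules:

* ``linear`` — LN neuron: ``r = dexp(x1)``;
* ``energy`` — quadrature-energy (phase-invariant) neuron:
  ``r = dexp(sqrt(x1^2 + x2^2))``, with the two filters a 90°-shifted
  Gabor pair;
* ``gain_control`` — ``r = dexp(x1) * exp(-beta * x2^2)``: energy on
  the second (suppressive) dimension divisively scales the response;
* ``and_gate`` — ``r = dexp(min(x1, x2))``: fires only when both
  filters are driven.

Projections are centered and jointly scaled (one RMS scale across a
neuron's dimensions, so quadrature symmetry is preserved) before the
rule is applied.  Trial rasters are Poisson counts at the frame scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage

from .data import ResponseSet, Spectrogram
from .models import DoubleExpParams, double_exponential
from .subspace import TuningSubspace, _project_values

__all__ = [
    "GroundTruthNeuron",
    "SyntheticDataset",
    "gabor_filter",
    "quadrature_pair",
    "generate_stimulus",
    "simulate_population",
    "subspace_recovery_error",
    "default_population",
]


def gabor_filter(n_channels: int = 32, n_lags: int = 25, f0: float = 0.5,
                 u0: float = 0.3, sigma_f: float = 4.0, sigma_u: float = 4.0,
                 omega_f: float = 0.0, omega_u: float = 0.08,
                 phase: float = 0.0) -> np.ndarray:
    """Unit-norm Gabor ripple on the (channel, lag) grid.

    ``f0``/``u0`` are fractional positions of the envelope center;
    ``omega_f``/``omega_u`` are modulation frequencies in cycles per
    channel / per lag bin.
    """
    f = np.arange(n_channels)[:, None]
    u = np.arange(n_lags)[None, :]
    env = np.exp(-0.5 * (((f - f0 * n_channels) / sigma_f) ** 2
                         + ((u - u0 * n_lags) / sigma_u) ** 2))
    carrier = np.cos(2 * np.pi * (omega_f * f + omega_u * u) + phase)
    g = env * carrier
    g -= g.mean()
    return g / np.linalg.norm(g)


def quadrature_pair(n_channels: int = 32, n_lags: int = 25, f0: float = 0.5,
                    u0: float = 0.3, sigma_f: float = 4.0, sigma_u: float = 4.0,
                    omega_f: float = 0.0, omega_u: float = 0.08,
                    phase: float = 0.0) -> np.ndarray:
    """Real and imaginary parts of one complex Gabor, ``(2, F, U)``.

    Built from a single complex carrier so the pair is exactly 90° apart,
    and scaled by one joint factor (mean squared norm = 1) rather than
    per-filter — per-filter normalization would slightly break the
    rotation symmetry that makes energy responses phase-invariant.
    """
    f = np.arange(n_channels)[:, None]
    u = np.arange(n_lags)[None, :]
    env = np.exp(-0.5 * (((f - f0 * n_channels) / sigma_f) ** 2
                         + ((u - u0 * n_lags) / sigma_u) ** 2))
    carrier = np.exp(1j * (2 * np.pi * (omega_f * f + omega_u * u) + phase))
    g = env * carrier
    g -= g.mean()
    pair = np.stack([g.real, g.imag])
    scale = np.sqrt(np.mean(np.sum(pair.reshape(2, -1) ** 2, axis=1)))
    return pair / scale


@dataclass
class GroundTruthNeuron:
    """A neuron with known filters and a known combination rule."""

    kind: str
    filters: np.ndarray                    # (n_filters, F, U), unit-norm rows
    out_nl: DoubleExpParams = field(default_factory=lambda: DoubleExpParams(
        b=0.05, a=1.0, s=0.0, k=1.0))
    beta: float = 4.0                      # suppression strength (gain_control)
    rate_scale: float = 50.0               # spikes/s at nonlinearity output 1

    _KINDS = ("linear", "energy", "gain_control", "and_gate")
    _MIN_FILTERS = {"linear": 1, "energy": 2, "gain_control": 2, "and_gate": 2}

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        self.filters = np.asarray(self.filters, dtype=float)
        if self.filters.ndim == 2:
            self.filters = self.filters[None]
        if self.filters.shape[0] < self._MIN_FILTERS[self.kind]:
            raise ValueError(f"{self.kind} neuron needs at least "
                             f"{self._MIN_FILTERS[self.kind]} filters")
        if self.rate_scale < 0:
            raise ValueError("rate_scale must be non-negative")
        flat = self.filters.reshape(self.filters.shape[0], -1)
        if self.kind == "energy":
            # joint scale keeps the quadrature pair exactly 90° symmetric
            scale = np.sqrt(np.mean(np.sum(flat ** 2, axis=1)))
            self.filters = self.filters / scale
        else:
            self.filters = self.filters / np.linalg.norm(flat, axis=1)[:, None, None]

    def rate(self, x: np.ndarray) -> np.ndarray:
        """Firing rate (spikes/s) from standardized projections ``(K, T)``."""
        if self.kind == "linear":
            base = double_exponential(x[0], self.out_nl)
        elif self.kind == "energy":
            base = double_exponential(np.sqrt(x[0] ** 2 + x[1] ** 2), self.out_nl)
        elif self.kind == "gain_control":
            base = double_exponential(x[0], self.out_nl) * np.exp(-self.beta * x[1] ** 2)
        else:  # and_gate
            base = double_exponential(np.minimum(x[0], x[1]), self.out_nl)
        return self.rate_scale * base


@dataclass
class SyntheticDataset:
    stimulus: Spectrogram
    neurons: list
    true_rates: np.ndarray                 # (N, T), spikes/s
    responses: ResponseSet                 # psth = true rates, rasters = Poisson counts
    projections: list = field(default_factory=list)  # standardized (K, T) per neuron
    seed: int = 0


def _log_center_freqs(n_channels: int, f_low: float = 200.0,
                      f_high: float = 20000.0) -> np.ndarray:
    return np.geomspace(f_low, f_high, n_channels)


def generate_stimulus(kind: str = "smoothed_noise", params: dict | None = None,
                      seed: int = 0) -> Spectrogram:
    """Synthetic 32-channel spectrogram with controllable modulation content.

    Kinds
    -----
    ``smoothed_noise``
        Gaussian noise smoothed over channels and frames (params
        ``sigma_f``, ``sigma_t``), standardized — a stand-in with the
        broadband, smooth statistics of natural-segment sequences.
    ``ripple_mixture``
        Sum of drifting ripples; ``params["ripples"]`` is a list of
        ``(omega_t_hz, omega_f_cyc_per_channel, amplitude, phase)``.
    ``segment_sequence``
        Concatenated blocks of heterogeneous smoothed noise with a
        seeded uniform level rove, emulating the natural-segment design.
    """
    p = dict(params or {})
    n_channels = int(p.pop("n_channels", 32))
    n_frames = int(p.pop("n_frames", 1000))
    frame_rate = float(p.pop("frame_rate", 100.0))
    rng = np.random.default_rng(seed)
    freqs = _log_center_freqs(n_channels)
    if kind == "smoothed_noise":
        sigma_f = p.pop("sigma_f", 1.5)
        sigma_t = p.pop("sigma_t", 2.0)
        v = ndimage.gaussian_filter(rng.standard_normal((n_channels, n_frames)),
                                    (sigma_f, sigma_t), mode="wrap")
        v = (v - v.mean()) / v.std()
    elif kind == "ripple_mixture":
        ripples = p.pop("ripples", [(4.0, 0.1, 1.0, 0.0)])
        t = np.arange(n_frames)[None, :] / frame_rate
        f = np.arange(n_channels)[:, None]
        v = np.zeros((n_channels, n_frames))
        for wt, wf, amp, phase in ripples:
            v += amp * np.cos(2 * np.pi * (wt * t + wf * f) + phase)
        noise = p.pop("noise", 0.0)
        if noise:
            v += noise * rng.standard_normal(v.shape)
    elif kind == "segment_sequence":
        n_blocks = int(p.pop("n_blocks", 8))
        rove = float(p.pop("level_rove", 1.0))
        edges = np.linspace(0, n_frames, n_blocks + 1).astype(int)
        v = np.empty((n_channels, n_frames))
        for b in range(n_blocks):
            sig_f = rng.uniform(0.8, 3.0)
            sig_t = rng.uniform(0.8, 4.0)
            block = ndimage.gaussian_filter(
                rng.standard_normal((n_channels, edges[b + 1] - edges[b])),
                (sig_f, sig_t), mode="wrap")
            block = (block - block.mean()) / block.std()
            v[:, edges[b]:edges[b + 1]] = block + rng.uniform(-rove / 2, rove / 2)
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    return Spectrogram(values=v, frame_rate=frame_rate, center_freqs=freqs)


def _standardized_projections(neuron: GroundTruthNeuron, values: np.ndarray) -> np.ndarray:
    """Scale projections to unit joint RMS over the steady-state region.

    The ground-truth filters are zero-mean, so projections are already
    near zero-mean; a single rotation-invariant RMS scale (no per-dim
    centering) keeps quadrature-energy responses exactly phase-invariant.
    """
    x = _project_values(neuron.filters, values)
    warmup = neuron.filters.shape[-1] - 1
    steady = x[:, warmup:] if x.shape[1] > warmup else x
    scale = np.sqrt(np.mean(steady ** 2))
    if scale > 0:
        x = x / scale
    return x


def simulate_population(neurons: list, s: Spectrogram, n_trials: int = 10,
                        seed: int = 0) -> SyntheticDataset:
    """Generate noiseless rates and Poisson trial rasters for a population."""
    values = s.values
    rates, projections = [], []
    for neuron in neurons:
        if neuron.filters.shape[1] != values.shape[0]:
            raise ValueError("neuron filters do not match the stimulus channels")
        x = _standardized_projections(neuron, values)
        projections.append(x)
        rates.append(neuron.rate(x))
    true_rates = np.stack(rates)
    rng = np.random.default_rng(seed)
    lam = np.clip(true_rates / s.frame_rate, 0, None)
    rasters = rng.poisson(lam[None, :, :], size=(n_trials,) + true_rates.shape)
    responses = ResponseSet(psth=true_rates, frame_rate=s.frame_rate,
                            rasters=rasters)
    return SyntheticDataset(stimulus=s, neurons=list(neurons),
                            true_rates=true_rates, responses=responses,
                            projections=projections, seed=seed)


def subspace_recovery_error(true_filters: np.ndarray,
                            recovered: TuningSubspace | np.ndarray) -> np.ndarray:
    """Principal angles (degrees, ascending) between true and recovered spans."""
    tf = np.asarray(true_filters, dtype=float)
    A = tf.reshape(tf.shape[0], -1).T
    rf = recovered.flat() if isinstance(recovered, TuningSubspace) else \
        np.asarray(recovered, dtype=float).reshape(len(recovered), -1)
    B = rf.T
    angles = linalg.subspace_angles(A, B)
    return np.rad2deg(np.sort(angles))


def default_population(n_channels: int = 32, n_lags: int = 25) -> list:
    """Desk-scale reference population: two neurons of each response kind."""
    pairs = {
        "linear": [gabor_filter(n_channels, n_lags, f0=0.35, u0=0.25, omega_u=0.10)],
        "energy": quadrature_pair(n_channels=n_channels, n_lags=n_lags,
                                  f0=0.55, u0=0.25, omega_u=0.12),
        "gain_control": np.stack([
            gabor_filter(n_channels, n_lags, f0=0.4, u0=0.2, omega_u=0.10),
            gabor_filter(n_channels, n_lags, f0=0.7, u0=0.3, omega_f=0.08,
                         omega_u=0.0),
        ]),
        "and_gate": np.stack([
            gabor_filter(n_channels, n_lags, f0=0.3, u0=0.2, omega_u=0.08),
            gabor_filter(n_channels, n_lags, f0=0.6, u0=0.25, omega_u=0.08),
        ]),
    }
    second = {
        "linear": [gabor_filter(n_channels, n_lags, f0=0.6, u0=0.3, omega_f=0.06,
                                omega_u=0.0)],
        "energy": quadrature_pair(n_channels=n_channels, n_lags=n_lags,
                                  f0=0.4, u0=0.3, omega_f=0.08, omega_u=0.0),
        "gain_control": np.stack([
            gabor_filter(n_channels, n_lags, f0=0.5, u0=0.25, omega_u=0.12),
            gabor_filter(n_channels, n_lags, f0=0.35, u0=0.35, omega_f=0.05,
                         omega_u=0.05),
        ]),
        "and_gate": np.stack([
            gabor_filter(n_channels, n_lags, f0=0.45, u0=0.2, omega_f=0.04,
                         omega_u=0.06),
            gabor_filter(n_channels, n_lags, f0=0.65, u0=0.35, omega_u=0.10),
        ]),
    }
    pop = []
    for table in (pairs, second):
        for kind, filters in table.items():
            pop.append(GroundTruthNeuron(kind=kind, filters=np.asarray(filters)))
    return pop
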