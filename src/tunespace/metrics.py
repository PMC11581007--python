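"""Quantitative descriptors of tuning and model performance.

Implements the subspace similarity index (SSI), tuning symmetry index
(TSI), noise-corrected prediction correlation, signal correlation,
modulation power spectra of spectro-temporal filters, response-field
tiling with a shuffle control, and spike-width cell-type classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TuningCurve",
    "ResponseField",
    "tuning_curve",
    "noise_corrected_prediction_correlation",
    "signal_correlation",
    "subspace_similarity_index",
    "tuning_symmetry_index",
    "modulation_power_spectrum",
    "response_field",
    "tiling_overlap",
    "classify_spike_width",
]


@dataclass
class TuningCurve:
    """Marginal tuning curve: mean rate at 20 bins of one projection."""

    x_centers: np.ndarray
    y: np.ndarray
    occupancy: np.ndarray | None = None

    def __post_init__(self):
        self.x_centers = np.asarray(self.x_centers, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x_centers.shape != self.y.shape:
            raise ValueError("x_centers and y must have the same shape")


def tuning_curve(x: np.ndarray, rate: np.ndarray, n_bins: int = 20,
                 coverage: float = 0.99) -> TuningCurve:
    """Bin one projection into ``n_bins`` spanning its central ``coverage``
    fraction and average the rate per bin (empty bins interpolated)."""
    x = np.asarray(x, dtype=float).ravel()
    rate = np.asarray(rate, dtype=float).ravel()
    tail = 100.0 * (1.0 - coverage) / 2.0
    lo, hi = np.percentile(x, [tail, 100.0 - tail])
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    inside = (x >= lo) & (x <= hi)
    occ = np.bincount(idx[inside], minlength=n_bins)
    tot = np.bincount(idx[inside], weights=rate[inside], minlength=n_bins)
    y = np.full(n_bins, np.nan)
    y[occ > 0] = tot[occ > 0] / occ[occ > 0]
    if np.any(occ == 0) and np.any(occ > 0):
        y = np.interp(centers, centers[occ > 0], y[occ > 0])
    return TuningCurve(x_centers=centers, y=y, occupancy=occ)


def noise_corrected_prediction_correlation(pred: np.ndarray,
                                           raster: np.ndarray) -> float:
    """Prediction correlation normalized by the trial-to-trial noise ceiling.

    Implements CC_norm (Schoppe et al. 2016): the Pearson correlation of
    the prediction with the trial-mean PSTH, divided by the square root
    of the estimated fraction of PSTH variance attributable to signal,

        ``SP = (var(sum_trials) - sum_trials var) / (n (n - 1))``.

    When all trials are identical this reduces exactly to the plain
    Pearson correlation.  The result is clipped to [-1, 1].
    """
    pred = np.asarray(pred, dtype=float).ravel()
    raster = np.atleast_2d(np.asarray(raster, dtype=float))
    if raster.shape[0] < 2:
        raise ValueError("noise correction requires at least 2 trials")
    if raster.shape[1] != pred.shape[0]:
        raise ValueError("prediction and raster must share the time axis")
    if np.std(pred) == 0:
        warnings.warn("zero-variance prediction; returning 0", RuntimeWarning)
        return 0.0
    n = raster.shape[0]
    psth = raster.mean(axis=0)
    sp = (np.var(raster.sum(axis=0)) - raster.var(axis=1).sum()) / (n * (n - 1))
    if sp <= 0 or np.std(psth) == 0:
        warnings.warn("no detectable signal power; returning 0", RuntimeWarning)
        return 0.0
    cov = np.cov(pred, psth, bias=True)[0, 1]
    cc = cov / (np.std(pred) * np.sqrt(sp))
    return float(np.clip(cc, -1.0, 1.0))


def signal_correlation(psth_a: np.ndarray, psth_b: np.ndarray) -> float:
    """Pearson correlation between two PSTHs; NaN for constant input."""
    a = np.asarray(psth_a, dtype=float).ravel()
    b = np.asarray(psth_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("PSTHs must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant PSTH: signal correlation undefined", RuntimeWarning)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def _filters_of(sub) -> np.ndarray:
    flat = getattr(sub, "flat", None)
    if callable(flat):  # TuningSubspace (ndarray.flat is a flatiter, not callable)
        return flat()
    arr = np.asarray(sub, dtype=float)
    return arr.reshape(arr.shape[0], -1)


def subspace_similarity_index(sub_a, sub_b, n_filters: int = 4) -> float:
    """SSI: summed absolute filter correlations, normalized by min(M, N).

    ``SSI = sum_{m,n} |cc(g_a,m, g_b,n)| / min(M, N)`` over the first
    ``n_filters`` filters of each subspace (fewer if a subspace is
    smaller).  1 indicates complete overlap, 0 no overlap.  Absolute
    correlations make the index invariant to the arbitrary sign of PCA
    components.
    """
    fa = _filters_of(sub_a)[:n_filters]
    fb = _filters_of(sub_b)[:n_filters]
    if fa.shape[0] == 0 or fb.shape[0] == 0:
        raise ValueError("each subspace needs at least one filter")
    ca = fa - fa.mean(axis=1, keepdims=True)
    cb = fb - fb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ca, axis=1)
    nb = np.linalg.norm(cb, axis=1)
    cc = (ca / na[:, None]) @ (cb / nb[:, None]).T
    return float(np.abs(cc).sum() / min(fa.shape[0], fb.shape[0]))


def tuning_symmetry_index(curve: TuningCurve) -> float:
    """TSI of a marginal tuning curve.

    With derivative ``y'`` from adjacent-bin differences,

        ``TSI = 1 - |sum y'| / sum |y'|``  if the summed derivative above
        zero exceeds that below zero, else ``-1 + |sum y'| / sum |y'|``.

    +1: symmetric upward-facing; -1: symmetric downward-facing; 0:
    monotone (asymmetric).  Invariant to adding a constant to ``y`` and
    to positive rescaling.
    """
    y = np.asarray(curve.y, dtype=float)
    x = np.asarray(curve.x_centers, dtype=float)
    ok = np.isfinite(y)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError("TSI requires at least 3 occupied bins")
    dy = np.diff(y)
    xm = 0.5 * (x[1:] + x[:-1])
    tot = np.sum(np.abs(dy))
    if tot == 0:
        warnings.warn("flat tuning curve: TSI undefined", RuntimeWarning)
        return float("nan")
    ratio = np.abs(np.sum(dy)) / tot
    upward = np.sum(dy[xm > 0]) - np.sum(dy[xm < 0])
    return float(1.0 - ratio) if upward > 0 else float(-1.0 + ratio)


def modulation_power_spectrum(filt: np.ndarray, frame_rate: float = 100.0,
                              channels_per_octave: float = 6.0):
    """2-D modulation power spectrum of a spectro-temporal filter.

    Squared magnitude of the 2-D Fourier transform over (log-frequency,
    lag), fft-shifted, with axes in physical units: temporal modulation
    in Hz and spectral modulation in cycles/octave.

    Returns ``(power, temporal_freqs, spectral_freqs)``.
    """
    filt = np.asarray(filt, dtype=float)
    if not np.all(np.isfinite(filt)):
        raise ValueError("filter must be finite")
    F, U = filt.shape
    spec = np.fft.fftshift(np.fft.fft2(filt))
    power = np.abs(spec) ** 2
    wt = np.fft.fftshift(np.fft.fftfreq(U, d=1.0 / frame_rate))
    wf = np.fft.fftshift(np.fft.fftfreq(F, d=1.0 / channels_per_octave))
    return power, wt, wf


@dataclass
class ResponseField:
    """Grid mask where a neuron's site-level tuning surface exceeds 80% of max."""

    mask: np.ndarray
    neuron: int | str = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def response_field(surface, neuron: int | str = 0,
                   threshold: float = 0.8) -> ResponseField:
    """Mask of bins whose mean rate exceeds ``threshold`` of the occupied max."""
    occupied = surface.occupied
    rates = np.where(occupied, surface.mean_rate, -np.inf)
    peak = rates.max()
    mask = occupied & (surface.mean_rate > threshold * peak)
    return ResponseField(mask=mask, neuron=neuron)


def tiling_overlap(fields: list, n_shuffles: int = 100, seed: int = 0) -> dict:
    """Per-cell overlap of response fields and a shuffle control.

    The overlap map counts, per grid cell, how many units' fields cover
    it; ``max_overlap`` is the maximum count.  The shuffle control
    applies a seeded random toroidal translation to each mask (which
    preserves its shape and area exactly) and recomputes the maximum.
    ``fraction_max_overlap`` is ``max_overlap / n_units``.
    """
    if not fields:
        raise ValueError("tiling_overlap requires at least one response field")
    masks = [np.asarray(f.mask if isinstance(f, ResponseField) else f, dtype=bool)
             for f in fields]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("all response fields must share one grid")
    overlap = np.sum(masks, axis=0)
    max_overlap = int(overlap.max())
    rng = np.random.default_rng(seed)
    shuffled_max = np.empty(n_shuffles, dtype=int)
    for i in range(n_shuffles):
        acc = np.zeros(shape, dtype=int)
        for m in masks:
            shifts = (rng.integers(shape[0]), rng.integers(shape[1]))
            acc += np.roll(m, shifts, axis=(0, 1))
        shuffled_max[i] = acc.max()
    return {
        "overlap_map": overlap,
        "max_overlap": max_overlap,
        "fraction_max_overlap": max_overlap / len(masks),
        "shuffled_max_overlap": shuffled_max,
        "shuffled_fraction_max_overlap": shuffled_max / len(masks),
    }


def classify_spike_width(width: float, threshold: float = 0.35) -> str:
    """Classify a peak-to-trough spike width (ms) as narrow or regular.

    Narrow iff strictly below the threshold (0.35 ms for 64-channel
    probes, 0.375 ms for Neuropixels); a width exactly at the threshold
    is regular.
    """
    if width <= 0:
        raise ValueError("spike width must be positive")
    return "narrow" if width < threshold else "regular"
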