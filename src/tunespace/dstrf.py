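"""Dynamic STRF: locally linear approximation of a fitted model.

At every stimulus timepoint ``t`` the nonlinear encoding model is
approximated by the linear filter

    ``d_t(f, u) = d r(t) / d s(f, t - u)``,  ``u in [0, U)``

evaluated at the actual stimulus.  For a CNN this is the Jacobian of
the model output; for an LN model it reduces to the static filter
scaled by the time-varying slope of the output nonlinearity.  Jackknife
members each contribute a dSTRF estimate, combined by a shrinkage
average that attenuates coefficients with high across-member variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Spectrogram
from .fitting import JackknifeEnsemble

__all__ = [
    "DSTRFStack",
    "jacobian_dstrf",
    "finite_difference_dstrf",
    "shrinkage_average",
    "ensemble_dstrf",
]

DEFAULT_MAX_LAG = 25  # frames; 250 ms at the 100 Hz frame rate


@dataclass
class DSTRFStack:
    """Per-timepoint locally linear filters for one neuron.

    ``filters[j]`` is the ``(F, U)`` filter at frame ``times[j]``.
    """

    filters: np.ndarray
    times: np.ndarray
    neuron: int
    max_lag: int = DEFAULT_MAX_LAG
    stride: int = 1
    source_model: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        if self.filters.ndim != 3:
            raise ValueError("filters must be (times, channels, lags)")
        if not np.all(np.isfinite(self.filters)):
            raise ValueError("dSTRF contains non-finite entries")

    @property
    def n_times(self) -> int:
        return self.filters.shape[0]

    def flattened(self) -> np.ndarray:
        """(T, F*U) view used by the subspace PCA."""
        return self.filters.reshape(self.n_times, -1)


def _stim_values(s) -> np.ndarray:
    return s.values if isinstance(s, Spectrogram) else np.atleast_2d(np.asarray(s, float))


def jacobian_dstrf(model, s, neuron: int, times=None, stride: int = 1,
                   max_lag: int = DEFAULT_MAX_LAG, chunk: int = 512) -> DSTRFStack:
    """Exact dSTRF of ``model`` for one neuron by differentiation.

    Parameters
    ----------
    model
        Any encoding model exposing ``input_jacobian``; the Jacobian is
        evaluated at the actual stimulus.
    times
        Frame indices; defaults to every ``stride``-th frame.
    """
    values = _stim_values(s)
    T = values.shape[1]
    if times is None:
        times = np.arange(0, T, stride)
    times = np.asarray(times, dtype=int)
    if times.size and (times.min() < 0 or times.max() >= T):
        raise ValueError("requested times fall outside the stimulus")
    if not hasattr(model, "input_jacobian"):
        raise TypeError(
            f"model {type(model).__name__} exposes no input_jacobian; "
            "it is not differentiable end-to-end")
    out = np.empty((len(times), values.shape[0], max_lag))
    for lo in range(0, len(times), chunk):
        batch = times[lo:lo + chunk]
        out[lo:lo + len(batch)] = model.input_jacobian(values, neuron, batch,
                                                       max_lag=max_lag)
    return DSTRFStack(filters=out, times=times, neuron=neuron, max_lag=max_lag,
                      stride=stride, source_model=type(model).__name__)


def finite_difference_dstrf(model, s, neuron: int, t: int, step: float = 1e-3,
                            max_lag: int = DEFAULT_MAX_LAG) -> np.ndarray:
    """Central-difference estimate of the dSTRF at one frame (test oracle).

    Perturbs every ``(f, t-u)`` stimulus bin by ``+-step`` and evaluates
    ``[r(s + step) - r(s - step)] / (2 step)``; exact for linear models
    and O(step^2) accurate for smooth nonlinear ones.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    values = _stim_values(s).copy()
    F = values.shape[0]
    # frames after t cannot matter (causality): truncate to keep the oracle cheap
    seg = values[:, : t + 1]
    t_loc = t
    out = np.zeros((F, max_lag))
    for u in range(max_lag):
        tt = t_loc - u
        if tt < 0:
            break
        for f in range(F):
            orig = seg[f, tt]
            seg[f, tt] = orig + step
            hi = model.predict(seg)[neuron, t_loc]
            seg[f, tt] = orig - step
            lo = model.predict(seg)[neuron, t_loc]
            seg[f, tt] = orig
            out[f, u] = (hi - lo) / (2.0 * step)
    return out


def shrinkage_average(estimates: np.ndarray) -> np.ndarray:
    """Variance-penalized average of jackknife dSTRF estimates.

    ``estimates`` stacks ``n >= 2`` estimates along axis 0.  Per
    coefficient, with mean ``m`` and standard error ``se``, the output is
    ``m * max(0, 1 - (se/|m|)^2)`` — coefficients whose standard error
    exceeds their mean magnitude are zeroed; the shrinkage never flips a
    sign and never increases a magnitude.
    """
    estimates = np.asarray(estimates, dtype=float)
    if estimates.shape[0] < 2:
        raise ValueError("shrinkage requires at least 2 estimates")
    n = estimates.shape[0]
    m = estimates.mean(axis=0)
    se = estimates.std(axis=0, ddof=1) / np.sqrt(n)
    absm = np.abs(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(absm > 0, 1.0 - (se / np.where(absm > 0, absm, 1.0)) ** 2, 0.0)
    return m * np.maximum(factor, 0.0)


def ensemble_dstrf(ensemble: JackknifeEnsemble, s, neuron: int, times=None,
                   stride: int = 1, max_lag: int = DEFAULT_MAX_LAG,
                   denormalize: bool = True) -> DSTRFStack:
    """Shrinkage-averaged dSTRF across all jackknife members.

    The stimulus is normalized with the ensemble's stored maps, each
    member's Jacobian is computed, and the per-coefficient shrinkage
    average is returned as a single stack.  With ``denormalize`` the
    Jacobian is chain-ruled back to physical units
    (``d r_raw / d s_raw = scale_r / scale_s(f) * d r_norm / d s_norm``),
    undoing the per-channel min-max scaling so filters are comparable
    across models and to ground truth.
    """
    values = _stim_values(s)
    if ensemble.stim_maps is not None:
        values = ensemble.stim_maps.apply(values)
    stacks = [jacobian_dstrf(m, values, neuron, times=times, stride=stride,
                             max_lag=max_lag)
              for m in ensemble.members]
    combined = shrinkage_average(np.stack([st.filters for st in stacks]))
    if denormalize:
        if ensemble.resp_maps is not None:
            scale_r = ensemble.resp_maps.scales[neuron]
            combined = combined * (scale_r if scale_r > 0 else 1.0)
        if ensemble.stim_maps is not None:
            scale_s = np.where(ensemble.stim_maps.scales > 0,
                               ensemble.stim_maps.scales, 1.0)
            combined = combined / scale_s[None, :, None]
    ref = stacks[0]
    return DSTRFStack(filters=combined, times=ref.times, neuron=neuron,
                      max_lag=max_lag, stride=stride,
                      source_model=f"ensemble[{len(stacks)}]")
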