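"""Low-level numerical primitives shared by all encoding models.

All models in this package are small enough (tens of thousands of
parameters) that forward passes, analytic gradients and input Jacobians
are implemented directly in numpy.  Conventions:

* spectrograms / multichannel series are ``(channels, time)`` arrays;
* causal convolution means output at frame ``t`` depends only on input
  frames ``<= t`` (zero left-padding);
* all filters are stored with lag axis last, ``w[..., u]`` applying to
  the input ``u`` frames in the past.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "causal_windows",
    "causal_conv",
    "causal_conv_input_grad",
    "causal_conv_weight_grad",
    "channelwise_causal_conv",
    "channelwise_conv_grads",
    "relu",
    "relu_grad",
    "Adam",
]


def causal_windows(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Return windows ``w[c, t, k] = x[c, t - (n_lags - 1) + k]`` (zero padded).

    ``x[c, t - u]`` is ``w[c, t, n_lags - 1 - u]``.
    """
    xp = np.pad(x, ((0, 0), (n_lags - 1, 0)))
    return sliding_window_view(xp, n_lags, axis=1)


def causal_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Causal 1-D convolution over time with channel mixing.

    ``z[o, t] = sum_{i, u} w[o, i, u] * x[i, t - u] (+ b[o])`` with zero
    left-padding; ``x`` is ``(C_in, T)``, ``w`` is ``(C_out, C_in, U)``.
    """
    n_lags = w.shape[-1]
    win = causal_windows(x, n_lags)
    z = np.einsum("itk,oik->ot", win, w[:, :, ::-1], optimize=True)
    if b is not None:
        z += b[:, None]
    return z


def causal_conv_input_grad(g: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gradient of a causal conv w.r.t. its input.

    ``dx[i, t] = sum_{o, u} w[o, i, u] * g[o, t + u]`` — a correlation with
    zero right-padding.  ``g`` is ``(C_out, T)``.
    """
    n_lags = w.shape[-1]
    gp = np.pad(g, ((0, 0), (0, n_lags - 1)))
    win = sliding_window_view(gp, n_lags, axis=1)  # (C_out, T, U)
    return np.einsum("otk,oik->it", win, w, optimize=True)


def causal_conv_weight_grad(g: np.ndarray, x: np.ndarray, n_lags: int) -> np.ndarray:
    """Gradient of a causal conv w.r.t. its weights, ``(C_out, C_in, U)``."""
    win = causal_windows(x, n_lags)
    gw = np.einsum("ot,itk->oik", g, win, optimize=True)
    return gw[:, :, ::-1]


def channelwise_causal_conv(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Per-channel causal temporal filter: ``z[m, t] = sum_u taps[m, u] x[m, t-u]``."""
    n_lags = taps.shape[-1]
    win = causal_windows(x, n_lags)
    return np.einsum("mtk,mk->mt", win, taps[:, ::-1], optimize=True)


def channelwise_conv_grads(g: np.ndarray, x: np.ndarray, taps: np.ndarray):
    """Gradients of :func:`channelwise_causal_conv` w.r.t. taps and input."""
    n_lags = taps.shape[-1]
    win = causal_windows(x, n_lags)
    gtaps = np.einsum("mtk,mt->mk", win, g, optimize=True)[:, ::-1]
    gp = np.pad(g, ((0, 0), (0, n_lags - 1)))
    gwin = sliding_window_view(gp, n_lags, axis=1)
    gx = np.einsum("mtk,mk->mt", gwin, taps, optimize=True)
    return gtaps, gx


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0.0).astype(z.dtype)


class Adam:
    """Plain Adam optimizer over a dict of named numpy parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self._t
        corr2 = 1.0 - b2 ** self._t
        for name, g in grads.items():
            if name not in self._m:
                self._m[name] = np.zeros_like(g)
                self._v[name] = np.zeros_like(g)
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[name] -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
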