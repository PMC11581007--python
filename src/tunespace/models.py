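"""Forward computations of the encoding-model families.

Three families live here:

* :class:`LNModel` — linear-nonlinear spectro-temporal receptive field
  model built from a shared bank of M rank-1 FIR filters, per-neuron
  readout weights and a double-exponential output nonlinearity.
* :class:`PopulationCNN` — the four-layer population convolutional
  model: two causal 1-D convolution layers, two dense layers, ReLU
  between layers, double-exponential output per neuron.
* :class:`PolyReadout` — first/second-order polynomial readout applied
  to subspace projections.

The nonlinear models expose a common training interface consumed by
:mod:`tunespace.fitting`:

``forward(values, stage)``
    returns ``(prediction, cache)``; ``stage`` is ``"level"`` (output
    nonlinearity replaced by a per-neuron level shift, used for the
    coarse fitting stage) or ``"full"``.
``backward(cache, g_out, stage)``
    returns a dict of parameter gradients for that stage.
``input_jacobian(values, neuron, times, max_lag)``
    returns the exact derivative of the stage-``full`` output at the
    requested frames with respect to the input, the quantity the dSTRF
    analysis consumes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from ._nnops import (
    causal_conv,
    causal_conv_input_grad,
    causal_conv_weight_grad,
    causal_windows,
    channelwise_causal_conv,
    channelwise_conv_grads,
    relu,
    relu_grad,
)

__all__ = [
    "DoubleExpParams",
    "double_exponential",
    "double_exponential_grad_x",
    "LNModel",
    "PopulationCNN",
    "PolyReadout",
    "poly_readout_forward",
]

_EXP_CLIP = 60.0


@dataclass
class DoubleExpParams:
    """Parameters of the double-exponential (Gompertz) output nonlinearity.

    ``r(x) = b + a * exp(-exp(-k * (x - s)))`` — ``b`` baseline rate,
    ``a`` response amplitude (saturation is ``b + a``), ``s`` threshold
    location, ``k`` gain.  Monotone increasing for ``k > 0``.
    """

    b: np.ndarray | float = 0.0
    a: np.ndarray | float = 1.0
    s: np.ndarray | float = 0.0
    k: np.ndarray | float = 1.0

    def __post_init__(self):
        for name in ("b", "a", "s", "k"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"double-exponential parameter {name!r} must be finite")
        if np.any(np.asarray(self.a) < 0):
            raise ValueError("amplitude a must be non-negative")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: np.atleast_1d(np.asarray(getattr(self, n), dtype=float))
                for n in ("b", "a", "s", "k")}


def _inner_exp(x, s, k):
    return np.exp(np.clip(-k * (x - s), -_EXP_CLIP, _EXP_CLIP))


def double_exponential(x, p: DoubleExpParams):
    """Evaluate the double-exponential nonlinearity elementwise."""
    e = _inner_exp(np.asarray(x, dtype=float), p.s, p.k)
    return p.b + p.a * np.exp(-e)


def double_exponential_grad_x(x, p: DoubleExpParams):
    """Derivative ``dr/dx`` of the double-exponential at ``x``."""
    x = np.asarray(x, dtype=float)
    e = _inner_exp(x, p.s, p.k)
    return p.a * np.exp(-e) * e * p.k


def _dexp_forward(x, b, a, s, k):
    e = np.exp(np.clip(-k[:, None] * (x - s[:, None]), -_EXP_CLIP, _EXP_CLIP))
    return b[:, None] + a[:, None] * np.exp(-e), e


def _dexp_backward(g, x, e, b, a, s, k):
    """Backprop through the output nonlinearity; returns (gx, gb, ga, gs, gk)."""
    ee = np.exp(-e)
    gx = g * a[:, None] * ee * e * k[:, None]
    gb = g.sum(axis=1)
    ga = (g * ee).sum(axis=1)
    gs = -gx.sum(axis=1)
    gk = (g * a[:, None] * ee * e * (x - s[:, None])).sum(axis=1)
    return gx, gb, ga, gs, gk


class _EncodingModelBase:
    """Shared parameter plumbing for the trainable models."""

    params: dict[str, np.ndarray]
    n_out: int

    def clone(self):
        return copy.deepcopy(self)

    def out_nl(self) -> DoubleExpParams:
        p = self.params
        return DoubleExpParams(p["b"], p["a"], p["s"], p["k"])

    def init_out_nl(self, rates: np.ndarray, drive: np.ndarray | None = None) -> None:
        """Initialize the output nonlinearity from response statistics.

        ``b`` = mean rate and ``a`` = rate range per neuron; the threshold
        ``s`` and gain ``k`` default to (0, 1) but, when the linear drive
        from the coarse fitting stage is supplied, are centered and
        scaled to its distribution so the sigmoid starts in its sensitive
        range instead of saturated.
        """
        rates = np.atleast_2d(rates)
        self.params["b"] = rates.mean(axis=1).copy()
        rng = np.ptp(rates, axis=1)
        self.params["a"] = np.where(rng > 0, rng, 1.0)
        if drive is None:
            self.params["s"] = np.zeros(self.n_out)
            self.params["k"] = np.ones(self.n_out)
        else:
            drive = np.atleast_2d(drive)
            spread = drive.std(axis=1)
            self.params["s"] = drive.mean(axis=1).copy()
            # cap the gain so sparse/low-variance drives cannot start the
            # sigmoid fully saturated (vanishing gradients)
            k = np.where(spread > 0, 2.0 / np.maximum(spread, 1e-6), 1.0)
            self.params["k"] = np.clip(k, 0.5, 8.0)

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Predicted rates ``(n_out, T)`` for a ``(channels, T)`` input."""
        pred, _ = self.forward(np.asarray(values, dtype=float), stage="full")
        return pred

    def _finalize_stage(self, z, stage):
        p = self.params
        if stage == "level":
            return z + p["shift"][:, None], None
        out, e = _dexp_forward(z, p["b"], p["a"], p["s"], p["k"])
        return out, e

    def _out_backward(self, g, z, e, stage, grads):
        p = self.params
        if stage == "level":
            grads["shift"] = g.sum(axis=1)
            return g
        gz, gb, ga, gs, gk = _dexp_backward(g, z, e, p["b"], p["a"], p["s"], p["k"])
        grads.update(b=gb, a=ga, s=gs, k=gk)
        return gz


class LNModel(_EncodingModelBase):
    """Population linear-nonlinear STRF model with rank-1 filterbank.

    The first stage convolves the spectrogram with a bank of ``M``
    rank-1 FIR filters ``h_m(f, u) = phi_m(f) * tau_m(u)``; per-neuron
    weights ``w`` mix the M filter outputs into a linear drive that is
    passed through the double-exponential nonlinearity.
    """

    #: parameters entering the L2 penalty (linear weights only)
    l2_keys = ("phi", "tau", "w")
    drive_key = "rlin"  # cache entry holding the pre-nonlinearity drive

    def __init__(self, n_neurons: int, n_filters: int = 100, n_channels: int = 32,
                 n_lags: int = 25, seed: int | None = 0, output: str = "dexp"):
        if output not in ("dexp", "identity"):
            raise ValueError("output must be 'dexp' or 'identity'")
        self.n_out = n_neurons
        self.n_filters = n_filters
        self.n_channels = n_channels
        self.n_lags = n_lags
        self.output = output  # 'identity' yields a purely linear model
        self.params: dict[str, np.ndarray] = {}
        self.init_params(np.random.default_rng(seed))

    @property
    def footprint(self) -> int:
        return self.n_lags

    def init_params(self, rng: np.random.Generator) -> None:
        M, F, U, N = self.n_filters, self.n_channels, self.n_lags, self.n_out
        self.params = {
            "phi": rng.uniform(-1, 1, (M, F)) / np.sqrt(F),
            "tau": rng.uniform(-1, 1, (M, U)) / np.sqrt(U),
            "w": rng.uniform(-1, 1, (N, M)) / np.sqrt(M),
            "shift": np.zeros(N),
            "b": np.zeros(N),
            "a": np.ones(N),
            "s": np.zeros(N),
            "k": np.ones(N),
        }

    def trainable_keys(self, stage: str):
        if stage == "level":
            return ("phi", "tau", "w", "shift")
        return ("phi", "tau", "w", "b", "a", "s", "k")

    def materialized_filters(self) -> np.ndarray:
        """Dense ``(M, F, U)`` filterbank (outer products of the rank-1 profiles)."""
        p = self.params
        return np.einsum("mf,mu->mfu", p["phi"], p["tau"])

    def effective_filters(self) -> np.ndarray:
        """Per-neuron effective STRF ``(N, F, U)``: weighted sum of the bank."""
        p = self.params
        return np.einsum("nm,mf,mu->nfu", p["w"], p["phi"], p["tau"], optimize=True)

    def forward(self, s: np.ndarray, stage: str = "full"):
        if s.shape[0] != self.n_channels:
            raise ValueError(
                f"stimulus has {s.shape[0]} channels, model expects {self.n_channels}"
            )
        p = self.params
        sp = p["phi"] @ s                    # (M, T) spectral projection
        rm = channelwise_causal_conv(sp, p["tau"])
        rlin = p["w"] @ rm                   # (N, T)
        if getattr(self, "output", "dexp") == "identity" and stage == "full":
            out, e = rlin, None
        else:
            out, e = self._finalize_stage(rlin, stage)
        cache = {"s": s, "sp": sp, "rm": rm, "rlin": rlin, "e": e}
        return out, cache

    def backward(self, cache, g_out: np.ndarray, stage: str = "full"):
        p = self.params
        grads: dict[str, np.ndarray] = {}
        if getattr(self, "output", "dexp") == "identity" and stage == "full":
            g_lin = g_out
        else:
            g_lin = self._out_backward(g_out, cache["rlin"], cache["e"], stage, grads)
        grads["w"] = g_lin @ cache["rm"].T
        g_rm = p["w"].T @ g_lin
        gtau, g_sp = channelwise_conv_grads(g_rm, cache["sp"], p["tau"])
        grads["tau"] = gtau
        grads["phi"] = g_sp @ cache["s"].T
        return grads

    def linear_drive(self, s: np.ndarray) -> np.ndarray:
        p = self.params
        return p["w"] @ channelwise_causal_conv(p["phi"] @ s, p["tau"])

    def input_jacobian(self, s: np.ndarray, neuron: int, times: np.ndarray,
                       max_lag: int | None = None) -> np.ndarray:
        """Exact ``d r_i(t) / d s(f, t-u)``, shape ``(len(times), F, max_lag)``.

        For the LN model this is the static effective filter scaled by the
        time-varying slope of the output nonlinearity.
        """
        max_lag = max_lag or self.n_lags
        times = np.asarray(times, dtype=int)
        h = self.effective_filters()[neuron]  # (F, U)
        if getattr(self, "output", "dexp") == "identity":
            gain = np.ones(len(times))
        else:
            rlin = self.linear_drive(s)[neuron]
            p = self.out_nl()
            gain = double_exponential_grad_x(
                rlin[times], DoubleExpParams(*(np.atleast_1d(getattr(p, n))[neuron]
                                               for n in ("b", "a", "s", "k"))))
        jac = np.zeros((len(times), s.shape[0], max_lag))
        u = min(max_lag, self.n_lags)
        jac[:, :, :u] = gain[:, None, None] * h[None, :, :u]
        return jac


class PopulationCNN(_EncodingModelBase):
    """Four-layer causal population CNN encoding model.

    Layer 1: ``conv1_filters`` causal filters over all input channels and
    ``conv1_lags`` time taps; layer 2: same over layer-1 output; layers
    3-4 dense per-frame maps; ReLU between layers; per-neuron
    double-exponential output.  Default widths follow the full-scale
    architecture (80, 100, 100); reduced widths are used for desk-scale
    work.
    """

    l2_keys = ("W1", "W2", "W3", "W4")
    drive_key = "z4"

    def __init__(self, n_neurons: int, n_channels: int = 32,
                 conv1_filters: int = 80, conv1_lags: int = 15,
                 conv2_filters: int = 100, conv2_lags: int = 10,
                 dense_width: int = 100, seed: int | None = 0):
        self.n_out = n_neurons
        self.n_channels = n_channels
        self.conv1_filters = conv1_filters
        self.conv1_lags = conv1_lags
        self.conv2_filters = conv2_filters
        self.conv2_lags = conv2_lags
        self.dense_width = dense_width
        self.params: dict[str, np.ndarray] = {}
        self.init_params(np.random.default_rng(seed))

    @property
    def footprint(self) -> int:
        """Temporal footprint in frames: perturbations older than this never matter."""
        return self.conv1_lags + self.conv2_lags - 1

    def init_params(self, rng: np.random.Generator) -> None:
        F, C1, K1 = self.n_channels, self.conv1_filters, self.conv1_lags
        C2, K2, H, N = self.conv2_filters, self.conv2_lags, self.dense_width, self.n_out

        def u(shape, fan_in):
            return rng.uniform(-1, 1, shape) * np.sqrt(3.0 / fan_in)

        self.params = {
            "W1": u((C1, F, K1), F * K1), "b1": np.zeros(C1),
            "W2": u((C2, C1, K2), C1 * K2), "b2": np.zeros(C2),
            "W3": u((H, C2), C2), "b3": np.zeros(H),
            "W4": u((N, H), H), "b4": np.zeros(N),
            "shift": np.zeros(N),
            "b": np.zeros(N), "a": np.ones(N), "s": np.zeros(N), "k": np.ones(N),
        }

    def trainable_keys(self, stage: str):
        base = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")
        if stage == "level":
            return base + ("shift",)
        return base + ("b", "a", "s", "k")

    def forward(self, s: np.ndarray, stage: str = "full"):
        if s.shape[0] != self.n_channels:
            raise ValueError(
                f"stimulus has {s.shape[0]} channels, model expects {self.n_channels}"
            )
        p = self.params
        z1 = causal_conv(s, p["W1"], p["b1"])
        a1 = relu(z1)
        z2 = causal_conv(a1, p["W2"], p["b2"])
        a2 = relu(z2)
        z3 = p["W3"] @ a2 + p["b3"][:, None]
        a3 = relu(z3)
        z4 = p["W4"] @ a3 + p["b4"][:, None]
        out, e = self._finalize_stage(z4, stage)
        cache = {"s": s, "z1": z1, "a1": a1, "z2": z2, "a2": a2,
                 "z3": z3, "a3": a3, "z4": z4, "e": e}
        return out, cache

    def backward(self, cache, g_out: np.ndarray, stage: str = "full"):
        p = self.params
        grads: dict[str, np.ndarray] = {}
        g4 = self._out_backward(g_out, cache["z4"], cache["e"], stage, grads)
        grads["W4"] = g4 @ cache["a3"].T
        grads["b4"] = g4.sum(axis=1)
        g3 = (p["W4"].T @ g4) * relu_grad(cache["z3"])
        grads["W3"] = g3 @ cache["a2"].T
        grads["b3"] = g3.sum(axis=1)
        g2 = (p["W3"].T @ g3) * relu_grad(cache["z2"])
        grads["W2"] = causal_conv_weight_grad(g2, cache["a1"], self.conv2_lags)
        grads["b2"] = g2.sum(axis=1)
        g1 = causal_conv_input_grad(g2, p["W2"]) * relu_grad(cache["z1"])
        grads["W1"] = causal_conv_weight_grad(g1, cache["s"], self.conv1_lags)
        grads["b1"] = g1.sum(axis=1)
        return grads

    def input_jacobian(self, s: np.ndarray, neuron: int, times: np.ndarray,
                       max_lag: int | None = None) -> np.ndarray:
        """Exact Jacobian of the output at ``times`` w.r.t. the input.

        Computed by back-propagating a unit seed from output ``(neuron, t)``
        through the network, batched over ``times``; returns
        ``(len(times), F, max_lag)`` with lag axis ``u`` meaning input frame
        ``t - u``.  Entries at lags beyond the architecture footprint are
        exactly zero.
        """
        max_lag = max_lag or self.footprint
        times = np.asarray(times, dtype=int)
        p = self.params
        _, cache = self.forward(s, stage="full")
        B = len(times)
        F, K1, K2 = self.n_channels, self.conv1_lags, self.conv2_lags

        pp = self.out_nl()
        e = cache["e"][neuron, times]
        a = np.atleast_1d(np.asarray(pp.a, dtype=float))
        k = np.atleast_1d(np.asarray(pp.k, dtype=float))
        a_i = a[neuron] if a.size > 1 else a[0]
        k_i = k[neuron] if k.size > 1 else k[0]
        gout = a_i * np.exp(-e) * e * k_i  # (B,) slope of out_nl at each time

        g3 = gout[:, None] * p["W4"][neuron][None, :] * relu_grad(cache["z3"][:, times]).T
        g2 = (g3 @ p["W3"]) * relu_grad(cache["z2"][:, times]).T  # (B, C2)

        # gather z1 windows z1[c, t-j] for j in 0..K2-1
        z1p = np.pad(cache["z1"], ((0, 0), (K2 - 1, 0)))
        idx = times[:, None] + (K2 - 1) - np.arange(K2)[None, :]  # padded index of t-j
        z1win = z1p[:, idx]                       # (C1, B, K2)
        mask1 = relu_grad(np.moveaxis(z1win, 0, 1))  # (B, C1, K2)
        gz1 = np.einsum("bo,ocj->bcj", g2, p["W2"], optimize=True) * mask1  # (B, C1, K2)

        jac = np.zeros((B, F, max(max_lag, K1 + K2 - 1)))
        for j in range(K2):
            jac[:, :, j:j + K1] += np.einsum(
                "bc,cfk->bfk", gz1[:, :, j], p["W1"], optimize=True)
        return jac[:, :, :max_lag]


@dataclass
class PolyReadout:
    """Polynomial map from subspace projections to rate.

    ``r(t) = sum_ij w_ij x_i(t) x_j(t) + sum_i v_i x_i(t) + r0`` with a
    symmetric second-order coefficient matrix; order 1 forces ``w = 0``
    (an affine map).
    """

    order: int
    v: np.ndarray
    w: np.ndarray | None = None
    r0: float = 0.0

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        self.v = np.asarray(self.v, dtype=float)
        d = len(self.v)
        if self.w is None:
            self.w = np.zeros((d, d))
        self.w = np.asarray(self.w, dtype=float)
        if self.order == 1 and np.any(self.w != 0):
            raise ValueError("order-1 readout must have zero second-order terms")
        if not np.allclose(self.w, self.w.T):
            raise ValueError("second-order coefficients must be symmetric")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return poly_readout_forward(self, x)


def poly_readout_forward(readout: PolyReadout, x: np.ndarray) -> np.ndarray:
    """Evaluate a polynomial readout on projections ``x`` of shape ``(D, T)``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(readout.v):
        raise ValueError(
            f"projection has {x.shape[0]} dimensions, readout expects {len(readout.v)}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("projections must be finite")
    r = readout.v @ x + readout.r0
    if readout.order == 2:
        r = r + np.einsum("ij,it,jt->t", readout.w, x, x, optimize=True)
    return r
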