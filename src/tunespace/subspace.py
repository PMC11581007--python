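"""Tuning-subspace analysis: PCA of dSTRFs, projections, readout models.

The collection of dSTRFs for a neuron is reduced by uncentered PCA
(SVD of the ``T x (F*U)`` stack) to the N leading components reaching a
cumulative explained-variance threshold (default 90%).  The stimulus is
projected onto each subspace filter by causal convolution, and a new
compact readout model — a two-layer dense network or a first/second
order polynomial — is fit from the projections to the neuron's rate.
Tuning surfaces and marginal curves are the binned mean response over
the projection values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._nnops import relu, relu_grad
from .data import ResponseSet, Spectrogram
from .dstrf import DSTRFStack
from .fitting import FitConfig, fit_population_model
from .models import PolyReadout, _EncodingModelBase

__all__ = [
    "TuningSubspace",
    "SubspaceProjection",
    "SubspaceReadout",
    "TuningSurface",
    "pca_subspace",
    "project_stimulus",
    "fit_subspace_readout",
    "estimate_tuning_surface",
]


@dataclass
class TuningSubspace:
    """Ordered orthonormal spectro-temporal filters spanning a neuron's tuning.

    ``filters[j]`` is the ``(F, U)`` filter of component ``j``;
    ``explained_variance`` is the cumulative variance fraction of the
    full component sequence (not just the retained ones).
    """

    filters: np.ndarray
    explained_variance: np.ndarray
    var_threshold: float = 0.90
    neuron: int | str = 0

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        if self.filters.ndim != 3:
            raise ValueError("filters must be (components, channels, lags)")
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]

    def flat(self) -> np.ndarray:
        return self.filters.reshape(self.n_components, -1)


@dataclass
class SubspaceProjection:
    """Projections ``x[j, t]`` of a stimulus onto subspace filters."""

    x: np.ndarray
    subspace_id: int | str = 0
    stimulus_id: str = ""

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if not np.all(np.isfinite(self.x)):
            raise ValueError("projections contain non-finite values")

    @property
    def n_dims(self) -> int:
        return self.x.shape[0]


def pca_subspace(stack: DSTRFStack | np.ndarray, var_threshold: float = 0.90,
                 neuron: int | str | None = None,
                 n_keep: int | None = None) -> TuningSubspace:
    """Uncentered PCA of a dSTRF stack.

    SVD of the ``T x (F*U)`` matrix without mean subtraction, so the
    subspace contains the mean dSTRF (the LN-like component).  Components
    are ordered by singular value; each filter's sign is fixed so that
    its largest-magnitude coefficient is positive.  ``n_keep`` overrides
    the threshold rule (smallest N with cumulative variance >= threshold).
    """
    if isinstance(stack, DSTRFStack):
        X = stack.flattened()
        shape = stack.filters.shape[1:]
        if neuron is None:
            neuron = stack.neuron
    else:
        arr = np.asarray(stack, dtype=float)
        X = arr.reshape(arr.shape[0], -1)
        shape = arr.shape[1:]
    if X.shape[0] == 0 or not np.any(X):
        raise ValueError("degenerate dSTRF: stack is empty or all-zero")
    _, sv, vt = np.linalg.svd(X, full_matrices=False)
    power = sv ** 2
    ev = np.cumsum(power) / power.sum()
    if n_keep is None:
        n_keep = int(np.searchsorted(ev, var_threshold - 1e-12) + 1)
    n_keep = min(n_keep, vt.shape[0])
    comps = vt[:n_keep]
    signs = np.sign(comps[np.arange(n_keep), np.argmax(np.abs(comps), axis=1)])
    comps = comps * np.where(signs == 0, 1.0, signs)[:, None]
    return TuningSubspace(filters=comps.reshape((n_keep,) + shape),
                          explained_variance=ev, var_threshold=var_threshold,
                          neuron=neuron if neuron is not None else 0)


def _project_values(filters: np.ndarray, values: np.ndarray) -> np.ndarray:
    """x[j, t] = sum_{f,u} g_j(f, u) s(f, t-u), zero left-padding."""
    n_lags = filters.shape[-1]
    pad = np.pad(values, ((0, 0), (n_lags - 1, 0)))
    win = sliding_window_view(pad, n_lags, axis=1)  # (F, T, U) win[f,t,k]=s[f,t-(U-1)+k]
    return np.einsum("ftk,jfk->jt", win, filters[:, :, ::-1], optimize=True)


def project_stimulus(sub: TuningSubspace, s) -> SubspaceProjection:
    """Project a stimulus into the tuning subspace (Eq.-5-style convolution)."""
    values = s.values if isinstance(s, Spectrogram) else np.atleast_2d(np.asarray(s, float))
    if values.shape[0] != sub.filters.shape[1]:
        raise ValueError(
            f"stimulus has {values.shape[0]} channels, subspace filters expect "
            f"{sub.filters.shape[1]}")
    return SubspaceProjection(x=_project_values(sub.filters, values),
                              subspace_id=sub.neuron)


class SubspaceReadout(_EncodingModelBase):
    """Two-layer dense readout from subspace projections to rate.

    ReLU hidden layers (default widths 30 and 20) followed by the
    double-exponential output; trains under the standard fitting
    protocol with the projections playing the role of the stimulus.
    """

    l2_keys = ("A1", "A2", "A3")
    drive_key = "z3"

    def __init__(self, n_dims: int, hidden: tuple[int, int] = (30, 20),
                 n_neurons: int = 1, seed: int | None = 0):
        if n_dims < 1:
            raise ValueError("readout requires a subspace with at least 1 dimension")
        self.n_dims = n_dims
        self.hidden = tuple(hidden)
        self.n_out = n_neurons
        self.params: dict[str, np.ndarray] = {}
        self.init_params(np.random.default_rng(seed))

    def init_params(self, rng: np.random.Generator) -> None:
        d, (h1, h2), n = self.n_dims, self.hidden, self.n_out

        def u(shape, fan_in):
            return rng.uniform(-1, 1, shape) * np.sqrt(3.0 / fan_in)

        self.params = {
            "A1": u((h1, d), d), "c1": np.zeros(h1),
            "A2": u((h2, h1), h1), "c2": np.zeros(h2),
            "A3": u((n, h2), h2), "c3": np.zeros(n),
            "shift": np.zeros(n),
            "b": np.zeros(n), "a": np.ones(n), "s": np.zeros(n), "k": np.ones(n),
        }

    def trainable_keys(self, stage: str):
        base = ("A1", "c1", "A2", "c2", "A3", "c3")
        if stage == "level":
            return base + ("shift",)
        return base + ("b", "a", "s", "k")

    def forward(self, x: np.ndarray, stage: str = "full"):
        if x.shape[0] != self.n_dims:
            raise ValueError(
                f"projection has {x.shape[0]} dims, readout expects {self.n_dims}")
        p = self.params
        z1 = p["A1"] @ x + p["c1"][:, None]
        a1 = relu(z1)
        z2 = p["A2"] @ a1 + p["c2"][:, None]
        a2 = relu(z2)
        z3 = p["A3"] @ a2 + p["c3"][:, None]
        out, e = self._finalize_stage(z3, stage)
        cache = {"x": x, "z1": z1, "a1": a1, "z2": z2, "a2": a2, "z3": z3, "e": e}
        return out, cache

    def backward(self, cache, g_out: np.ndarray, stage: str = "full"):
        p = self.params
        grads: dict[str, np.ndarray] = {}
        g3 = self._out_backward(g_out, cache["z3"], cache["e"], stage, grads)
        grads["A3"] = g3 @ cache["a2"].T
        grads["c3"] = g3.sum(axis=1)
        g2 = (p["A3"].T @ g3) * relu_grad(cache["z2"])
        grads["A2"] = g2 @ cache["a1"].T
        grads["c2"] = g2.sum(axis=1)
        g1 = (p["A2"].T @ g2) * relu_grad(cache["z1"])
        grads["A1"] = g1 @ cache["x"].T
        grads["c1"] = g1.sum(axis=1)
        return grads


def _fit_poly(x: np.ndarray, r: np.ndarray, order: int, ridge: float) -> PolyReadout:
    """Closed-form ridge fit of a polynomial readout (linear in parameters)."""
    d, T = x.shape
    feats = [np.ones(T), *x]
    if order == 2:
        for i in range(d):
            for j in range(i, d):
                feats.append(x[i] * x[j])
    A = np.stack(feats, axis=1)  # (T, P)
    reg = ridge * np.eye(A.shape[1])
    reg[0, 0] = 0.0  # do not penalize the intercept
    coef = np.linalg.solve(A.T @ A + reg * T, A.T @ r)
    r0 = float(coef[0])
    v = coef[1:1 + d]
    w = np.zeros((d, d))
    if order == 2:
        k = 1 + d
        for i in range(d):
            for j in range(i, d):
                if i == j:
                    w[i, i] = coef[k]
                else:
                    w[i, j] = w[j, i] = coef[k] / 2.0
                k += 1
    return PolyReadout(order=order, v=v, w=w, r0=r0)


def fit_subspace_readout(x: SubspaceProjection | np.ndarray, r, cfg: FitConfig | None = None,
                         order: str = "dense",
                         hidden: tuple[int, int] = (30, 20)):
    """Fit a readout model from subspace projections to a neuron's rate.

    ``order`` selects the model class: ``"dense"`` (two-layer network,
    fitted with the full two-stage jackknife protocol — returns a
    :class:`~tunespace.fitting.JackknifeEnsemble`) or ``"poly1"`` /
    ``"poly2"`` (polynomial readouts, linear in their parameters, fitted
    in closed form by ridge least squares — returns a
    :class:`~tunespace.models.PolyReadout`).
    """
    cfg = cfg or FitConfig()
    xv = x.x if isinstance(x, SubspaceProjection) else np.atleast_2d(np.asarray(x, float))
    rv = r.psth if isinstance(r, ResponseSet) else np.atleast_2d(np.asarray(r, float))
    if xv.shape[0] == 0:
        raise ValueError("cannot fit a readout on an empty (N=0) subspace")
    if xv.shape[1] != rv.shape[1]:
        raise ValueError("projections and response must share the same frames")
    if order == "dense":
        template = SubspaceReadout(n_dims=xv.shape[0], hidden=hidden,
                                   n_neurons=rv.shape[0])
        return fit_population_model(template, xv, rv, cfg)
    if order in ("poly1", "poly2"):
        if rv.shape[0] != 1:
            raise ValueError("polynomial readouts are fit per neuron")
        return _fit_poly(xv, rv[0], order=int(order[-1]), ridge=cfg.l2_strength)
    raise ValueError(f"unknown readout order {order!r}")


@dataclass
class TuningSurface:
    """Binned mean response over one or two subspace projections."""

    dims: tuple
    edges: list
    mean_rate: np.ndarray
    occupancy: np.ndarray
    min_occupancy: int = 5

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy >= self.min_occupancy

    @property
    def centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


def _central_edges(values: np.ndarray, n_bins: int, coverage: float) -> np.ndarray:
    tail = 100.0 * (1.0 - coverage) / 2.0
    lo, hi = np.percentile(values, [tail, 100.0 - tail])
    if hi <= lo:
        hi = lo + 1e-12
    return np.linspace(lo, hi, n_bins + 1)


def estimate_tuning_surface(x: SubspaceProjection | np.ndarray, rate: np.ndarray,
                            dims=(0, 1), n_bins: int = 25, coverage: float = 0.99,
                            min_occupancy: int = 5) -> TuningSurface:
    """Mean response at each point of the (1- or 2-D) projection grid.

    Bins span the central ``coverage`` fraction (default 99%) of each
    projection; bins with fewer than ``min_occupancy`` samples are
    flagged empty and should be excluded from downstream maxima.
    """
    xv = x.x if isinstance(x, SubspaceProjection) else np.atleast_2d(np.asarray(x, float))
    rate = np.asarray(rate, dtype=float).ravel()
    if rate.shape[0] != xv.shape[1]:
        raise ValueError("rate length must match the projection")
    if np.isscalar(dims) or isinstance(dims, (int, np.integer)):
        dims = (int(dims),)
    dims = tuple(int(d) for d in dims)
    coords = [xv[d] for d in dims]
    edges = [_central_edges(c, n_bins, coverage) for c in coords]
    occupancy, _ = np.histogramdd(np.stack(coords, axis=1), bins=edges)
    total, _ = np.histogramdd(np.stack(coords, axis=1), bins=edges, weights=rate)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rate = np.where(occupancy > 0, total / np.where(occupancy > 0, occupancy, 1), np.nan)
    return TuningSurface(dims=dims, edges=edges, mean_rate=mean_rate,
                         occupancy=occupancy.astype(int), min_occupancy=min_occupancy)
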