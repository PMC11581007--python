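"""Model fitting: normalization, two-stage Adam schedule, jackknifing.

The protocol applied to every trainable encoding model:

1. stimulus and response channels are min-max normalized to [0, 1]
   using statistics of the fit data only;
2. a coarse stage optimizes the linear parameters with the output
   nonlinearity replaced by a per-neuron level shift (learning rate
   0.01, stop tolerance 1e-3);
3. the double-exponential output is restored (initialized from response
   statistics) and fitting continues at learning rate 1e-3, tolerance
   1e-4;
4. an ``n_jackknife``-fold procedure excludes a distinct contiguous
   block (12.5% at the 8-fold default) from the fit data on each fold;
   each fold is fit from ``n_inits`` seeded random initializations and
   the initialization with the lowest loss on the fold's excluded bins
   is retained.

Loss is mean squared error over all neurons simultaneously plus an L2
penalty on linear weights (never on output-nonlinearity parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nnops import Adam
from .data import ResponseSet, Spectrogram

__all__ = [
    "FitConfig",
    "MinMaxMaps",
    "normalize_minmax",
    "JackknifeEnsemble",
    "fit_population_model",
]

log = logging.getLogger(__name__)


@dataclass
class FitConfig:
    coarse_lr: float = 0.01
    coarse_tol: float = 1e-3
    fine_lr: float = 0.001
    fine_tol: float = 1e-4
    l2_strength: float = 1e-4
    n_jackknife: int = 8
    n_inits: int = 5
    seed: int = 0
    max_epochs: int = 600
    patience: int = 50
    min_epochs: int = 50  # guard against stopping during the Adam transient

    def __post_init__(self):
        if self.coarse_lr <= 0 or self.fine_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.coarse_tol <= 0 or self.fine_tol <= 0:
            raise ValueError("stop tolerances must be positive")
        if self.n_jackknife < 2:
            raise ValueError("n_jackknife must be at least 2")
        if self.n_inits < 1:
            raise ValueError("n_inits must be at least 1")


@dataclass
class MinMaxMaps:
    """Per-channel affine maps taking data to [0, 1] and back."""

    mins: np.ndarray
    scales: np.ndarray  # max - min; 0 for constant channels

    def apply(self, x: np.ndarray) -> np.ndarray:
        safe = np.where(self.scales > 0, self.scales, 1.0)
        return (x - self.mins[:, None]) / safe[:, None]

    def invert(self, x: np.ndarray) -> np.ndarray:
        safe = np.where(self.scales > 0, self.scales, 1.0)
        return x * safe[:, None] + self.mins[:, None]


def normalize_minmax(data: np.ndarray) -> tuple[np.ndarray, MinMaxMaps]:
    """Normalize each channel (row) of ``data`` to the range [0, 1].

    Returns the normalized matrix and the affine maps needed to apply the
    identical transform to validation data or to invert it.  A constant
    channel maps to all zeros (degenerate rule) and inverts exactly.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    mins = data.min(axis=1)
    scales = data.max(axis=1) - mins
    maps = MinMaxMaps(mins=mins, scales=scales)
    return maps.apply(data), maps


@dataclass
class JackknifeEnsemble:
    """A set of jackknife-fitted models plus the normalization maps."""

    members: list
    fold_masks: np.ndarray          # (n_folds, T) bool, True = excluded on that fold
    diagnostics: list = field(default_factory=list)
    stim_maps: MinMaxMaps | None = None
    resp_maps: MinMaxMaps | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def _stim_values(self, s) -> np.ndarray:
        values = s.values if isinstance(s, Spectrogram) else np.asarray(s, dtype=float)
        if self.stim_maps is not None:
            values = self.stim_maps.apply(values)
        return values

    def member_predict(self, index: int, s, denormalize: bool = True) -> np.ndarray:
        pred = self.members[index].predict(self._stim_values(s))
        if denormalize and self.resp_maps is not None:
            pred = self.resp_maps.invert(pred)
        return pred

    def predict(self, s, denormalize: bool = True) -> np.ndarray:
        """Ensemble prediction: mean over jackknife members, ``(N, T)``."""
        values = self._stim_values(s)
        preds = np.stack([m.predict(values) for m in self.members])
        pred = preds.mean(axis=0)
        if denormalize and self.resp_maps is not None:
            pred = self.resp_maps.invert(pred)
        return pred


def make_fold_masks(n_frames: int, n_folds: int, seed: int) -> np.ndarray:
    """Disjoint, exhaustive contiguous-block exclusion masks.

    Contiguous blocks (rather than interleaved bins) respect the temporal
    correlation of both stimulus and response.  The block-to-fold
    assignment is a seeded permutation.
    """
    edges = np.linspace(0, n_frames, n_folds + 1).astype(int)
    order = np.random.default_rng(seed).permutation(n_folds)
    masks = np.zeros((n_folds, n_frames), dtype=bool)
    for fold, block in enumerate(order):
        masks[fold, edges[block]:edges[block + 1]] = True
    return masks


def _loss_and_grads(model, s, r, include, cfg: FitConfig, stage: str):
    pred, cache = model.forward(s, stage=stage)
    resid = (pred - r) * include[None, :]
    n_fit = r.shape[0] * max(int(include.sum()), 1)
    mse = float(np.sum(resid * resid) / n_fit)
    l2 = 0.0
    for key in model.l2_keys:
        l2 += float(np.sum(model.params[key] ** 2))
    loss = mse + cfg.l2_strength * l2
    grads = model.backward(cache, 2.0 * resid / n_fit, stage=stage)
    for key in model.l2_keys:
        if key in grads:
            grads[key] = grads[key] + 2.0 * cfg.l2_strength * model.params[key]
    keep = set(model.trainable_keys(stage))
    grads = {k: v for k, v in grads.items() if k in keep}
    return loss, grads, pred


def _train_stage(model, s, r, include, exclude, stage, lr, tol, cfg: FitConfig):
    """Full-batch Adam with early stopping on the excluded (validation) bins."""
    opt = Adam(lr)
    n_val = max(int(exclude.sum()), 1)
    best_hist: list[float] = []
    epoch = 0
    for epoch in range(cfg.max_epochs):
        loss, grads, pred = _loss_and_grads(model, s, r, include, cfg, stage)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch} ({stage} stage)")
        vresid = (pred - r)[:, exclude]
        val = float(np.sum(vresid * vresid) / (r.shape[0] * n_val))
        best_hist.append(min(val, best_hist[-1]) if best_hist else val)
        # stop when the best validation loss improved by less than tol
        # (relative) over the last `patience` epochs
        if epoch >= max(cfg.patience, cfg.min_epochs):
            before = best_hist[-cfg.patience - 1]
            if before > 0 and (before - best_hist[-1]) / before < tol:
                break
        opt.step(model.params, grads)
    return {"final_loss": loss, "final_val": val, "epochs": epoch + 1}


def _fit_values(model_template, s_values, r_values, cfg: FitConfig) -> JackknifeEnsemble:
    T = s_values.shape[1]
    s_norm, stim_maps = normalize_minmax(s_values)
    r_norm, resp_maps = normalize_minmax(r_values)
    masks = make_fold_masks(T, cfg.n_jackknife, cfg.seed)

    members, diagnostics = [], []
    for fold in range(cfg.n_jackknife):
        exclude = masks[fold]
        include = ~exclude
        best = None
        fold_diag = []
        for init in range(cfg.n_inits):
            model = model_template.clone()
            rng = np.random.default_rng([abs(int(cfg.seed)), fold, init])
            model.init_params(rng)
            try:
                d1 = _train_stage(model, s_norm, r_norm, include, exclude,
                                  "level", cfg.coarse_lr, cfg.coarse_tol, cfg)
                _, cache = model.forward(s_norm, stage="level")
                model.init_out_nl(r_norm, drive=cache[model.drive_key])
                d2 = _train_stage(model, s_norm, r_norm, include, exclude,
                                  "full", cfg.fine_lr, cfg.fine_tol, cfg)
            except FloatingPointError as err:
                log.warning("fold %d init %d aborted: %s", fold, init, err)
                fold_diag.append({"init": init, "aborted": str(err)})
                continue
            score = d2["final_val"]
            fold_diag.append({"init": init, "coarse": d1, "fine": d2, "score": score})
            if best is None or score < best[0]:
                best = (score, model)
        if best is None:
            raise RuntimeError(f"all initializations failed for fold {fold}")
        members.append(best[1])
        diagnostics.append({"fold": fold, "inits": fold_diag, "best_score": best[0]})
    return JackknifeEnsemble(members=members, fold_masks=masks,
                             diagnostics=diagnostics,
                             stim_maps=stim_maps, resp_maps=resp_maps)


def fit_population_model(model, s, r, cfg: FitConfig | None = None) -> JackknifeEnsemble:
    """Fit an encoding model to a (stimulus, response) pair.

    Parameters
    ----------
    model
        A trainable model instance (e.g. :class:`~tunespace.models.LNModel`,
        :class:`~tunespace.models.PopulationCNN`, or a subspace readout)
        used as an architecture template; its parameters are re-initialized
        per fold and initialization.
    s
        :class:`~tunespace.data.Spectrogram` or ``(channels, T)`` array.
    r
        :class:`~tunespace.data.ResponseSet` or ``(N, T)`` array of rates.
    cfg
        Fit protocol configuration; defaults to :class:`FitConfig()`.
    """
    cfg = cfg or FitConfig()
    s_values = s.values if isinstance(s, Spectrogram) else np.atleast_2d(np.asarray(s, float))
    r_values = r.psth if isinstance(r, ResponseSet) else np.atleast_2d(np.asarray(r, float))
    if s_values.shape[1] != r_values.shape[1]:
        raise ValueError("stimulus and response must share the same number of frames")
    if isinstance(s, Spectrogram) and isinstance(r, ResponseSet) \
            and s.frame_rate != r.frame_rate:
        raise ValueError("stimulus and response must share the same frame rate")
    return _fit_values(model, s_values, r_values, cfg)
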