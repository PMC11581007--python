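"""End-to-end pipeline tying the stages into reproducible runs.

A :class:`RunConfig` lists the stages to execute (in the canonical
order simulate → fit → dstrf → subspace → readout → metrics) with one
parameter block per stage and a single global seed from which every
stage derives a named substream.  Outputs (HDF5 arrays, TSV metric
tables, a JSON report with content hashes and the effective config) are
written under the configured output directory; identical config + seed
reproduce identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .fitting import FitConfig, fit_population_model
from .dstrf import ensemble_dstrf
from .metrics import (signal_correlation, subspace_similarity_index,
                      tuning_curve, tuning_symmetry_index)
from .models import LNModel, PopulationCNN
from .subspace import fit_subspace_readout, pca_subspace, project_stimulus
from .synthetic import (default_population, generate_stimulus,
                        simulate_population, subspace_recovery_error)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

STAGE_ORDER = ("frontend", "simulate", "fit", "dstrf", "subspace", "readout",
               "metrics")
_TOP_KEYS = {"stages", "seed", "out_dir"} | set(STAGE_ORDER)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list
    seed: int = 0
    out_dir: str = "results"
    blocks: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = list(d.get("stages", ("simulate", "fit", "dstrf", "subspace",
                                       "readout", "metrics")))
        order = [STAGE_ORDER.index(s) for s in stages]  # raises on unknown stage
        if order != sorted(order):
            raise ValueError(f"stages must follow the order {STAGE_ORDER}")
        return cls(stages=stages, seed=int(d.get("seed", 0)),
                   out_dir=str(d.get("out_dir", "results")),
                   blocks={s: dict(d.get(s, {})) for s in stages})

    def stage_seed(self, stage: str) -> int:
        # named substream per stage derived from the single global seed
        return int(np.random.default_rng(
            [abs(self.seed), STAGE_ORDER.index(stage)]).integers(2 ** 31))


def _build_model(kind: str, n_neurons: int, n_channels: int, params: dict):
    if kind == "cnn":
        return PopulationCNN(n_neurons=n_neurons, n_channels=n_channels, **params)
    if kind == "ln":
        return LNModel(n_neurons=n_neurons, n_channels=n_channels, **params)
    raise ValueError(f"unknown model kind {kind!r}")


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages; returns the JSON-serializable report.

    On a stage failure the partial outputs written so far are retained
    and the failure is recorded in the report under the stage's name.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"format_version": tio.FORMAT_VERSION, "seed": config.seed,
                    "stages": {}, "config": {s: config.blocks.get(s, {})
                                             for s in config.stages}}
    state: dict = {}
    for stage in config.stages:
        t0 = time.time()
        block = config.blocks.get(stage, {})
        log.info("stage %s: %s", stage, block)
        try:
            info = _STAGES[stage](state, block, config, out)
        except Exception as err:  # retain partial outputs, record failure
            report["stages"][stage] = {"failed": str(err)}
            log.error("stage %s failed: %s", stage, err)
            break
        info["wall_s"] = round(time.time() - t0, 3)
        report["stages"][stage] = info
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _stage_simulate(state, block, config, out):
    seed = config.stage_seed("simulate")
    stim_kind = block.get("stimulus", "smoothed_noise")
    stim_params = dict(block.get("stimulus_params", {}))
    n_frames = int(block.get("n_frames", 4000))
    n_val = int(block.get("n_val_frames", max(400, n_frames // 10)))
    stim_params["n_frames"] = n_frames + n_val
    s = generate_stimulus(stim_kind, stim_params, seed=seed)
    kinds = block.get("kinds")
    pop = default_population(n_channels=s.n_channels)
    if kinds:
        pop = [n for n in pop if n.kind in kinds]
    ds = simulate_population(pop, s, n_trials=int(block.get("n_trials", 10)),
                             seed=seed + 1)
    state.update(dataset=ds, n_fit=n_frames)
    tio.save_spectrogram(s, out / "stimulus.h5")
    return {"n_neurons": len(pop), "n_frames": s.n_frames,
            "kinds": [n.kind for n in pop],
            "stimulus_hash": tio.content_hash(s.values)}


def _stage_fit(state, block, config, out):
    ds = state["dataset"]
    n_fit = state["n_fit"]
    cfg = FitConfig(seed=config.stage_seed("fit"),
                    **{k: v for k, v in block.get("fit_config", {}).items()})
    model = _build_model(block.get("model", "cnn"), ds.true_rates.shape[0],
                         ds.stimulus.n_channels, dict(block.get("architecture", {})))
    s_fit = ds.stimulus.slice_time(0, n_fit)
    r_fit = ds.true_rates[:, :n_fit]
    ensemble = fit_population_model(model, s_fit, r_fit, cfg)
    state["ensemble"] = ensemble
    tio.save_bundle(ensemble, out / "model_bundle")
    s_val = ds.stimulus.slice_time(n_fit, ds.stimulus.n_frames)
    pred = ensemble.predict(s_val)
    r_val = ds.true_rates[:, n_fit:]
    corr = [signal_correlation(pred[i], r_val[i]) for i in range(pred.shape[0])]
    state["val_pred"] = pred
    return {"model": block.get("model", "cnn"),
            "val_correlation": [round(float(c), 4) for c in corr]}


def _stage_dstrf(state, block, config, out):
    ds = state["dataset"]
    stride = int(block.get("stride", 2))
    max_lag = int(block.get("max_lag", 25))
    n_fit = state["n_fit"]
    stacks = {}
    for i in range(ds.true_rates.shape[0]):
        stacks[i] = ensemble_dstrf(state["ensemble"], ds.stimulus.slice_time(0, n_fit),
                                   i, stride=stride, max_lag=max_lag)
        tio.save_dstrf(stacks[i], out / "dstrf.h5")
    state["dstrf"] = stacks
    return {"n_neurons": len(stacks), "stride": stride,
            "hashes": {i: tio.content_hash(st.filters) for i, st in stacks.items()}}


def _stage_subspace(state, block, config, out):
    thr = float(block.get("var_threshold", 0.90))
    subs, projections = {}, {}
    for i, stack in state["dstrf"].items():
        subs[i] = pca_subspace(stack, var_threshold=thr, neuron=i)
        projections[i] = project_stimulus(subs[i], state["dataset"].stimulus)
        tio.save_subspace(subs[i], out / "subspace.h5")
    state["subspace"] = subs
    state["projections"] = projections
    return {"n_components": {i: s.n_components for i, s in subs.items()}}


def _stage_readout(state, block, config, out):
    ds = state["dataset"]
    n_fit = state["n_fit"]
    cfg = FitConfig(seed=config.stage_seed("readout"),
                    **{k: v for k, v in block.get("fit_config", {}).items()})
    order = block.get("order", "dense")
    readouts, corr = {}, {}
    for i, proj in state["projections"].items():
        x_fit, x_val = proj.x[:, :n_fit], proj.x[:, n_fit:]
        fitted = fit_subspace_readout(x_fit, ds.true_rates[i:i + 1, :n_fit], cfg,
                                      order=order)
        readouts[i] = fitted
        pred = (fitted.predict(x_val) if hasattr(fitted, "predict")
                else fitted.predict(x_val))
        pred = np.atleast_2d(pred)
        corr[i] = round(float(signal_correlation(pred[0], ds.true_rates[i, n_fit:])), 4)
    state["readouts"] = readouts
    return {"order": order, "val_correlation": corr}


def _stage_metrics(state, block, config, out):
    ds = state["dataset"]
    subs = state["subspace"]
    rows = []
    for i, sub in subs.items():
        proj = state["projections"][i]
        for j in range(sub.n_components):
            curve = tuning_curve(proj.x[j], ds.true_rates[i])
            rows.append({"neuron": i, "kind": ds.neurons[i].kind, "dim": j,
                         "tsi": tuning_symmetry_index(curve)})
    tsi_table = pd.DataFrame(rows)
    tsi_table.to_csv(out / "tsi.tsv", sep="\t", index=False)
    n = len(subs)
    ssi = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ssi[i, j] = subspace_similarity_index(subs[i], subs[j])
    pd.DataFrame(ssi).to_csv(out / "ssi.tsv", sep="\t", index=False)
    angles = {}
    for i, sub in subs.items():
        truth = ds.neurons[i].filters
        lags = min(truth.shape[-1], sub.filters.shape[-1])  # align lag axes
        angles[i] = [round(float(a), 3) for a in subspace_recovery_error(
            truth[:, :, :lags], sub.filters[:truth.shape[0], :, :lags])]
    return {"tsi_hash": tio.content_hash(tsi_table["tsi"].to_numpy()),
            "ssi_hash": tio.content_hash(ssi),
            "n_components": {i: s.n_components for i, s in subs.items()},
            "recovery_angles_deg": angles}


def _stage_frontend(state, block, config, out):
    raise ValueError("frontend stage requires waveform input; use the library "
                     "API (tunespace.frontend) or the `tunespace frontend` command")


_STAGES = {
    "frontend": _stage_frontend,
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "dstrf": _stage_dstrf,
    "subspace": _stage_subspace,
    "readout": _stage_readout,
    "metrics": _stage_metrics,
}
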