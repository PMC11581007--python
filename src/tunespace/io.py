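"""Serialization: model bundles (JSON metadata + HDF5 arrays) and HDF5
containers for spectrograms, dSTRF stacks and subspaces.

A bundle is a directory with ``meta.json`` (format version, model
class, architecture, content hashes) and ``arrays.h5`` (parameters).
The version check happens on the JSON metadata before any array is
read; a round trip reproduces predictions exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .data import Spectrogram
from .dstrf import DSTRFStack
from .fitting import JackknifeEnsemble, MinMaxMaps
from .models import LNModel, PolyReadout, PopulationCNN
from .subspace import SubspaceReadout, TuningSubspace

__all__ = [
    "FORMAT_VERSION",
    "save_bundle",
    "load_bundle",
    "content_hash",
    "save_spectrogram",
    "load_spectrogram",
    "save_dstrf",
    "load_dstrf",
    "save_subspace",
    "load_subspace",
]

FORMAT_VERSION = "1"


def content_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()[:16]


def _architecture(model) -> dict:
    if isinstance(model, LNModel):
        return {"class": "LNModel", "n_neurons": model.n_out,
                "n_filters": model.n_filters, "n_channels": model.n_channels,
                "n_lags": model.n_lags, "output": model.output}
    if isinstance(model, PopulationCNN):
        return {"class": "PopulationCNN", "n_neurons": model.n_out,
                "n_channels": model.n_channels,
                "conv1_filters": model.conv1_filters, "conv1_lags": model.conv1_lags,
                "conv2_filters": model.conv2_filters, "conv2_lags": model.conv2_lags,
                "dense_width": model.dense_width}
    if isinstance(model, SubspaceReadout):
        return {"class": "SubspaceReadout", "n_dims": model.n_dims,
                "hidden": list(model.hidden), "n_neurons": model.n_out}
    if isinstance(model, PolyReadout):
        return {"class": "PolyReadout", "order": model.order}
    raise TypeError(f"cannot bundle model of type {type(model).__name__}")


def _rebuild(meta: dict, arrays: dict):
    cls = meta["class"]
    if cls == "LNModel":
        m = LNModel(meta["n_neurons"], meta["n_filters"], meta["n_channels"],
                    meta["n_lags"], seed=None, output=meta.get("output", "dexp"))
    elif cls == "PopulationCNN":
        m = PopulationCNN(meta["n_neurons"], meta["n_channels"],
                          meta["conv1_filters"], meta["conv1_lags"],
                          meta["conv2_filters"], meta["conv2_lags"],
                          meta["dense_width"], seed=None)
    elif cls == "SubspaceReadout":
        m = SubspaceReadout(meta["n_dims"], tuple(meta["hidden"]),
                            meta["n_neurons"], seed=None)
    elif cls == "PolyReadout":
        return PolyReadout(order=meta["order"], v=arrays["v"], w=arrays["w"],
                           r0=float(arrays["r0"]))
    else:
        raise ValueError(f"unknown model class {cls!r} in bundle")
    m.params = {k: np.array(v) for k, v in arrays.items()}
    return m


def _model_arrays(model) -> dict:
    if isinstance(model, PolyReadout):
        return {"v": model.v, "w": model.w, "r0": np.array(model.r0)}
    return model.params


def save_bundle(model, path) -> None:
    """Persist a model or jackknife ensemble to a bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    is_ens = isinstance(model, JackknifeEnsemble)
    meta = {"format_version": FORMAT_VERSION}
    with h5py.File(path / "arrays.h5", "w") as f:
        if is_ens:
            meta["class"] = "JackknifeEnsemble"
            meta["members"] = []
            for i, member in enumerate(model.members):
                g = f.create_group(f"member_{i}")
                arrays = _model_arrays(member)
                for k, v in arrays.items():
                    g.create_dataset(k, data=v)
                meta["members"].append(_architecture(member))
            f.create_dataset("fold_masks", data=model.fold_masks)
            if model.stim_maps is not None:
                f.create_dataset("stim_mins", data=model.stim_maps.mins)
                f.create_dataset("stim_scales", data=model.stim_maps.scales)
            if model.resp_maps is not None:
                f.create_dataset("resp_mins", data=model.resp_maps.mins)
                f.create_dataset("resp_scales", data=model.resp_maps.scales)
            hashes = [content_hash(*_model_arrays(m).values()) for m in model.members]
        else:
            meta.update(_architecture(model))
            arrays = _model_arrays(model)
            for k, v in arrays.items():
                f.create_dataset(k, data=v)
            hashes = [content_hash(*arrays.values())]
    meta["content_hashes"] = hashes
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_bundle(path):
    """Load a bundle; refuses version mismatches before reading any array."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no bundle at {path} (missing {meta_path})")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {version!r} is not supported "
            f"(expected {FORMAT_VERSION!r}); refusing to read arrays")
    with h5py.File(path / "arrays.h5", "r") as f:
        if meta.get("class") == "JackknifeEnsemble":
            members = []
            for i, m_meta in enumerate(meta["members"]):
                arrays = {k: np.array(v) for k, v in f[f"member_{i}"].items()}
                members.append(_rebuild(m_meta, arrays))
            stim_maps = resp_maps = None
            if "stim_mins" in f:
                stim_maps = MinMaxMaps(np.array(f["stim_mins"]),
                                       np.array(f["stim_scales"]))
            if "resp_mins" in f:
                resp_maps = MinMaxMaps(np.array(f["resp_mins"]),
                                       np.array(f["resp_scales"]))
            return JackknifeEnsemble(members=members,
                                     fold_masks=np.array(f["fold_masks"]),
                                     stim_maps=stim_maps, resp_maps=resp_maps)
        arrays = {k: np.array(v) for k, v in f.items()}
    return _rebuild(meta, arrays)


def save_spectrogram(spec: Spectrogram, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("spectrogram")
        g.create_dataset("values", data=spec.values)
        if spec.center_freqs is not None:
            g.create_dataset("center_freqs", data=spec.center_freqs)
        g.attrs["frame_rate"] = spec.frame_rate


def load_spectrogram(path) -> Spectrogram:
    with h5py.File(path, "r") as f:
        g = f["spectrogram"]
        cf = np.array(g["center_freqs"]) if "center_freqs" in g else None
        return Spectrogram(values=np.array(g["values"]),
                           frame_rate=float(g.attrs["frame_rate"]),
                           center_freqs=cf)


def save_dstrf(stack: DSTRFStack, path) -> None:
    with h5py.File(path, "a") as f:
        name = f"dstrf/neuron_{stack.neuron}"
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("filters", data=stack.filters, compression="gzip")
        g.create_dataset("times", data=stack.times)
        g.attrs["max_lag"] = stack.max_lag
        g.attrs["stride"] = stack.stride
        g.attrs["model_hash"] = content_hash(stack.filters)
        g.attrs["source_model"] = stack.source_model


def load_dstrf(path, neuron) -> DSTRFStack:
    with h5py.File(path, "r") as f:
        g = f[f"dstrf/neuron_{neuron}"]
        return DSTRFStack(filters=np.array(g["filters"]),
                          times=np.array(g["times"]), neuron=neuron,
                          max_lag=int(g.attrs["max_lag"]),
                          stride=int(g.attrs["stride"]),
                          source_model=str(g.attrs["source_model"]))


def save_subspace(sub: TuningSubspace, path) -> None:
    with h5py.File(path, "a") as f:
        name = f"subspace/neuron_{sub.neuron}"
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("filters", data=sub.filters)
        g.create_dataset("explained_variance", data=sub.explained_variance)
        g.attrs["var_threshold"] = sub.var_threshold


def load_subspace(path, neuron) -> TuningSubspace:
    with h5py.File(path, "r") as f:
        g = f[f"subspace/neuron_{neuron}"]
        return TuningSubspace(filters=np.array(g["filters"]),
                              explained_variance=np.array(g["explained_variance"]),
                              var_threshold=float(g.attrs["var_threshold"]),
                              neuron=neuron)
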