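"""HDF5 containers for sessions, model checkpoints, and fixed-point sets.

Session layout (documented contract)::

    /fluorescence   float64 (trials, bins, neurons)
    /trial_type     variable-length str (trials,)
    /cue_bin        int scalar
    /neuron_ids     variable-length str (neurons,)
    attrs: bin_size (s), session_id

Model checkpoints store every parameter array under ``/params``, the
standardization vectors, and the configuration as a YAML string attribute.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import h5py
import numpy as np
import yaml

from .model import ModelConfig, TrainedModel
from .fixed_points import FixedPointSet
from .synth import SessionData

_STR = h5py.string_dtype()


def write_session(path, data: SessionData, latents: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("fluorescence", data=data.fluorescence)
        f.create_dataset(
            "trial_type", data=np.asarray(data.trial_type, dtype=object), dtype=_STR
        )
        f.create_dataset("cue_bin", data=int(data.cue_bin))
        f.create_dataset(
            "neuron_ids", data=np.asarray(data.neuron_ids, dtype=object), dtype=_STR
        )
        f.attrs["bin_size"] = float(data.bin_size)
        f.attrs["session_id"] = data.session_id
        if latents is not None:
            f.create_dataset("latents", data=latents)


def read_session(path) -> SessionData:
    with h5py.File(path, "r") as f:
        for name in ("fluorescence", "trial_type", "cue_bin"):
            if name not in f:
                raise KeyError(f"session file missing dataset '{name}'")
        for attr in ("bin_size", "session_id"):
            if attr not in f.attrs:
                raise KeyError(f"session file missing attribute '{attr}'")
        return SessionData(
            fluorescence=f["fluorescence"][()],
            trial_type=np.array(
                [s.decode() if isinstance(s, bytes) else s for s in f["trial_type"][()]],
                dtype=object,
            ),
            cue_bin=int(f["cue_bin"][()]),
            bin_size=float(f.attrs["bin_size"]),
            neuron_ids=(
                np.array(
                    [s.decode() if isinstance(s, bytes) else s for s in f["neuron_ids"][()]],
                    dtype=object,
                )
                if "neuron_ids" in f
                else None
            ),
            session_id=str(f.attrs["session_id"]),
        )


def save_model(path, model: TrainedModel) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for k, v in model.params.items():
            grp.create_dataset(k, data=v)
        f.create_dataset("data_mean", data=model.data_mean)
        f.create_dataset("data_std", data=model.data_std)
        f.attrs["config"] = yaml.safe_dump(dataclasses.asdict(model.config))
        f.attrs["n_neurons"] = model.n_neurons
        f.attrs["best_epoch"] = model.best_epoch
        curve = f.create_group("training_curve")
        for k, v in model.training_curve.items():
            curve.create_dataset(k, data=np.asarray(v))


def load_model(path) -> TrainedModel:
    with h5py.File(path, "r") as f:
        cfg = ModelConfig(**yaml.safe_load(f.attrs["config"]))
        params = {k: f["params"][k][()] for k in f["params"]}
        curve = {k: f["training_curve"][k][()].tolist() for k in f["training_curve"]}
        return TrainedModel(
            params=params,
            config=cfg,
            n_neurons=int(f.attrs["n_neurons"]),
            data_mean=f["data_mean"][()],
            data_std=f["data_std"][()],
            training_curve=curve,
            best_epoch=int(f.attrs["best_epoch"]),
        )


def save_fixed_points(path, fps: FixedPointSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("points", data=fps.points)
        f.create_dataset("speeds", data=fps.squared_speeds)
        f.create_dataset("eigenvalues", data=fps.jacobian_eigenvalues)
        f.create_dataset("reference_input", data=fps.reference_input)
        f.attrs["speed_threshold"] = fps.speed_threshold
        f.attrs["classification"] = fps.classification
        f.attrs["converged"] = fps.converged


def load_fixed_points(path) -> FixedPointSet:
    with h5py.File(path, "r") as f:
        return FixedPointSet(
            points=f["points"][()],
            squared_speeds=f["speeds"][()],
            jacobian_eigenvalues=f["eigenvalues"][()],
            reference_input=f["reference_input"][()],
            speed_threshold=float(f.attrs["speed_threshold"]),
            classification=str(f.attrs["classification"]),
            converged=bool(f.attrs["converged"]),
        )


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
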