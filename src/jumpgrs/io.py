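"""Serialization: model specs as JSON, checkpoints as ``.npz`` with a JSON
sidecar, datasets as CSV (label column first) and pruning configs as
JSON/YAML."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import LabeledDataset, ModelSpec, TrainConfig, TrainedModel
from .pruning import PruningConfig

__all__ = [
    "save_spec", "load_spec",
    "save_model", "load_model",
    "dataset_to_csv", "dataset_from_csv",
    "load_pruning_config",
]


def save_spec(spec: ModelSpec, path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2))


def load_spec(path) -> ModelSpec:
    return ModelSpec.from_dict(json.loads(Path(path).read_text()))


def save_model(model: TrainedModel, path) -> None:
    """Write ``<path>.npz`` (weights) and ``<path>.spec.json`` (architecture
    plus rng record)."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(model.weights):
        for k, v in layer.items():
            arrays[f"layer{i}_{k}"] = v
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    sidecar = {"spec": model.spec.to_dict(), "rng_state": model.rng_state,
               "n_layers": len(model.weights)}
    path.with_suffix(".spec.json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".spec.json").read_text())
    spec = ModelSpec.from_dict(sidecar["spec"])
    data = np.load(path.with_suffix(".npz"))
    weights = []
    for i in range(sidecar["n_layers"]):
        keys = [k for k in data.files if k.startswith(f"layer{i}_")]
        weights.append({k.split("_", 1)[1]: data[k] for k in keys})
    return TrainedModel(spec=spec, weights=weights,
                        rng_state=sidecar.get("rng_state", {}))


def dataset_to_csv(data: LabeledDataset, path) -> None:
    """Label column first, features flattened to ``f0..fK`` columns."""
    X = data.X.reshape(data.n, -1)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "label", data.y)
    df.to_csv(path, index=False)


def dataset_from_csv(path, feature_shape: tuple[int, ...] | None = None) -> LabeledDataset:
    df = pd.read_csv(path)
    y = df["label"].to_numpy()
    X = df.drop(columns="label").to_numpy(dtype=np.float64)
    if feature_shape is not None:
        X = X.reshape((len(y),) + tuple(feature_shape))
    return LabeledDataset(X, y)


def load_pruning_config(path) -> PruningConfig:
    """Read a pruning config from JSON or YAML."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    train_raw = raw.pop("train_cfg", {})
    return PruningConfig(train_cfg=TrainConfig(**train_raw), **{
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
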