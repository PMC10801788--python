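"""Trainable MLP/CNN classifiers with structured surgery and cost counting.

This module is the substrate that every pruning algorithm operates on.  It
provides:

* :class:`ModelSpec` / :class:`LayerSpec` — declarative architecture
  descriptions (dense and convolutional hidden layers, a softmax output).
* :class:`TrainedModel` — a spec plus concrete weight tensors.
* ``build_model`` / ``train`` / ``fine_tune`` / ``validate`` — seeded,
  deterministic construction, mini-batch Adam training and accuracy
  evaluation.
* ``remove_units`` — the structured-pruning surgery: deleting whole nodes
  (dense) or whole filters (conv) together with every dependent weight in
  the next layer, including the conv-to-dense flattening boundary.
* ``param_count`` / ``flop_count`` — model-size metrics under an explicit,
  documented convention.

Numerical note: the forward pass accumulates contributions one input unit at
a time, in a fixed order.  This makes unit removal *exact*: a hidden unit
whose outgoing weights are all zero contributes an exact floating-point zero
at each accumulation step, so deleting it leaves the logits bitwise
unchanged.  Gradients use ordinary vectorized linear algebra.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "LabeledDataset",
    "RemovalUnitRef",
    "ConfigurationError",
    "DataError",
    "StructureError",
    "CallCounters",
    "COUNTERS",
    "reset_counters",
    "build_model",
    "train",
    "fine_tune",
    "validate",
    "predict_logits",
    "remove_units",
    "param_count",
    "flop_count",
    "unit_counts",
]


class ConfigurationError(ValueError):
    """An inconsistent model spec or training configuration."""


class DataError(ValueError):
    """A dataset that does not match the model or is unusable (e.g. empty)."""


class StructureError(ValueError):
    """A surgery request that would produce an invalid structure."""


_ACTIVATIONS = ("relu", "tanh")


# ---------------------------------------------------------------------------
# specs and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One hidden layer: a dense layer of ``units`` nodes or a conv layer of
    ``units`` filters with the given ``kernel`` and optional max-pool size."""

    layer_kind: str  # "dense" | "conv"
    units: int
    kernel: tuple[int, int] = ()
    activation: str = "relu"
    pool: int | None = None

    def __post_init__(self):
        if self.layer_kind not in ("dense", "conv"):
            raise ConfigurationError(f"unknown layer kind {self.layer_kind!r}")
        if self.units < 1:
            raise ConfigurationError("layer must keep at least one unit")
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.layer_kind == "conv":
            if len(self.kernel) != 2 or any(k < 1 for k in self.kernel):
                raise ConfigurationError("conv layer needs a kernel (kh, kw) >= 1")
            if self.pool is not None and self.pool < 1:
                raise ConfigurationError("pool size must be >= 1")
        else:
            if self.kernel:
                raise ConfigurationError("dense layer takes no kernel")
            if self.pool is not None:
                raise ConfigurationError("dense layer takes no pooling")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of a classifier: input shape, ordered hidden layers,
    and a linear softmax output of ``num_classes`` logits.

    ``input_shape`` is ``(n_features,)`` for an MLP and
    ``(channels, height, width)`` for a CNN.  For CNNs all conv layers must
    precede all dense layers (dense layers sit at the output side).
    """

    kind: str  # "mlp" | "cnn"
    input_shape: tuple[int, ...]
    hidden_layers: tuple[LayerSpec, ...]
    num_classes: int = 2

    def __post_init__(self):
        object.__setattr__(self, "input_shape", tuple(int(v) for v in self.input_shape))
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))
        if self.kind not in ("mlp", "cnn"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if not self.hidden_layers:
            raise ConfigurationError("model needs at least one hidden layer")
        if self.num_classes < 2:
            raise ConfigurationError("need at least two classes")
        if any(v < 1 for v in self.input_shape):
            raise ConfigurationError("input dimensions must be positive")
        if self.kind == "mlp":
            if len(self.input_shape) != 1:
                raise ConfigurationError("mlp input_shape is (n_features,)")
            if any(l.layer_kind != "dense" for l in self.hidden_layers):
                raise ConfigurationError("mlp hidden layers must all be dense")
        else:
            if len(self.input_shape) != 3:
                raise ConfigurationError("cnn input_shape is (channels, height, width)")
            kinds = [l.layer_kind for l in self.hidden_layers]
            if kinds[0] != "conv":
                raise ConfigurationError("cnn must start with a conv layer")
            seen_dense = False
            for k in kinds:
                if k == "dense":
                    seen_dense = True
                elif seen_dense:
                    raise ConfigurationError("conv layer after dense layer")
            # spatial dims must stay positive
            self.conv_output_shape()

    @property
    def n_hidden(self) -> int:
        return len(self.hidden_layers)

    def conv_output_shape(self) -> tuple[int, int, int] | None:
        """(height, width, channels) after the last conv/pool stage, or None
        for an MLP.  Valid padding, stride 1, pool stride = pool size."""
        if self.kind == "mlp":
            return None
        c, h, w = self.input_shape
        for layer in self.hidden_layers:
            if layer.layer_kind != "conv":
                break
            kh, kw = layer.kernel
            h, w = h - kh + 1, w - kw + 1
            if h < 1 or w < 1:
                raise ConfigurationError("kernel larger than feature map")
            if layer.pool:
                h, w = h // layer.pool, w // layer.pool
                if h < 1 or w < 1:
                    raise ConfigurationError("pooling collapses the feature map")
            c = layer.units
        return h, w, c

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "input_shape": list(self.input_shape),
            "num_classes": self.num_classes,
            "hidden_layers": [
                {
                    "layer_kind": l.layer_kind,
                    "units": l.units,
                    "kernel": list(l.kernel),
                    "activation": l.activation,
                    "pool": l.pool,
                }
                for l in self.hidden_layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        layers = tuple(
            LayerSpec(
                layer_kind=l["layer_kind"],
                units=int(l["units"]),
                kernel=tuple(l.get("kernel") or ()),
                activation=l.get("activation", "relu"),
                pool=l.get("pool"),
            )
            for l in d["hidden_layers"]
        )
        return cls(
            kind=d["kind"],
            input_shape=tuple(d["input_shape"]),
            hidden_layers=layers,
            num_classes=int(d.get("num_classes", 2)),
        )


def mlp_spec(n_features: int, hidden: Sequence[int], num_classes: int = 2,
             activation: str = "relu") -> ModelSpec:
    """Convenience constructor for a plain MLP spec."""
    return ModelSpec(
        kind="mlp",
        input_shape=(n_features,),
        hidden_layers=tuple(LayerSpec("dense", u, activation=activation) for u in hidden),
        num_classes=num_classes,
    )


@dataclass(frozen=True)
class RemovalUnitRef:
    """A single removal unit: node/filter ``unit_index`` of hidden layer
    ``layer_index``.  Input features and output logits are never removal
    units."""

    layer_index: int
    unit_index: int


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    fine_tune_epochs: int = 2
    learning_rate: float = 0.01
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.fine_tune_epochs < 0:
            raise ConfigurationError("epoch counts must be positive")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ConfigurationError("learning rate and batch size must be positive")


@dataclass
class LabeledDataset:
    """A feature matrix/tensor with integer class labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise DataError("feature/label length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx])


@dataclass
class TrainedModel:
    """A spec plus per-layer weights.

    ``weights`` holds one dict per hidden layer plus the output layer, in
    order.  Dense: ``W`` of shape (fan_in, units), ``b`` of shape (units,).
    Conv: ``W`` of shape (kh, kw, in_channels, filters), ``b`` (filters,).
    ``rng_state`` records the seeds used to build/train the model.
    """

    spec: ModelSpec
    weights: list[dict]
    rng_state: dict = field(default_factory=dict)

    def copy(self) -> "TrainedModel":
        return TrainedModel(
            spec=self.spec,
            weights=[{k: v.copy() for k, v in layer.items()} for layer in self.weights],
            rng_state=copy.deepcopy(self.rng_state),
        )


# ---------------------------------------------------------------------------
# global call counters (hardware-independent speed proxy)
# ---------------------------------------------------------------------------

@dataclass
class CallCounters:
    train: int = 0
    fine_tune: int = 0
    validate: int = 0

    def snapshot(self) -> tuple[int, int, int]:
        return (self.train, self.fine_tune, self.validate)


COUNTERS = CallCounters()


def reset_counters() -> None:
    COUNTERS.train = COUNTERS.fine_tune = COUNTERS.validate = 0


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _layer_fan_ins(spec: ModelSpec) -> list[int]:
    """Fan-in (dense) or input-channel count (conv) for each hidden layer and
    the output layer (last element)."""
    fans: list[int] = []
    if spec.kind == "mlp":
        prev = spec.input_shape[0]
        for l in spec.hidden_layers:
            fans.append(prev)
            prev = l.units
        fans.append(prev)
        return fans
    c, h, w = spec.input_shape
    prev_dense = None
    for l in spec.hidden_layers:
        if l.layer_kind == "conv":
            fans.append(c)
            kh, kw = l.kernel
            h, w = h - kh + 1, w - kw + 1
            if l.pool:
                h, w = h // l.pool, w // l.pool
            c = l.units
        else:
            if prev_dense is None:
                prev_dense = h * w * c
            fans.append(prev_dense)
            prev_dense = l.units
    fans.append(prev_dense if prev_dense is not None else h * w * c)
    return fans


def build_model(spec: ModelSpec, seed: int) -> TrainedModel:
    """Initialise an untrained model; reproducible for a given seed.

    Dense/conv weights use Glorot-uniform (tanh) or He-normal (relu) scaling;
    biases start at zero.
    """
    rng = np.random.default_rng(seed)
    fans = _layer_fan_ins(spec)
    weights: list[dict] = []
    for i, layer in enumerate(spec.hidden_layers):
        fan_in = fans[i]
        if layer.layer_kind == "dense":
            weights.append({
                "W": _init(rng, (fan_in, layer.units), fan_in, layer.units, layer.activation),
                "b": np.zeros(layer.units),
            })
        else:
            kh, kw = layer.kernel
            eff_in = kh * kw * fan_in
            weights.append({
                "W": _init(rng, (kh, kw, fan_in, layer.units), eff_in, layer.units,
                           layer.activation),
                "b": np.zeros(layer.units),
            })
    weights.append({
        "W": _init(rng, (fans[-1], spec.num_classes), fans[-1], spec.num_classes, "tanh"),
        "b": np.zeros(spec.num_classes),
    })
    return TrainedModel(spec=spec, weights=weights, rng_state={"build_seed": int(seed)})


def _init(rng, shape, fan_in, fan_out, activation):
    if activation == "relu":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# forward pass (ordered accumulation — exact under zero-weight removal)
# ---------------------------------------------------------------------------

def _dense_apply(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.tile(b, (X.shape[0], 1))
    for k in range(W.shape[0]):
        out += X[:, k, None] * W[k]
    return out


def _conv_apply(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    # X: (n, H, W, C) channels-last; valid padding, stride 1
    n, H, Wd, C = X.shape
    kh, kw, _, F = W.shape
    oh, ow = H - kh + 1, Wd - kw + 1
    out = np.tile(b, (n, oh, ow, 1))
    for dy in range(kh):
        for dx in range(kw):
            for c in range(C):
                out += X[:, dy:dy + oh, dx:dx + ow, c, None] * W[dy, dx, c]
    return out


def _pool_apply(X: np.ndarray, p: int) -> np.ndarray:
    n, H, W, C = X.shape
    oh, ow = H // p, W // p
    v = X[:, : oh * p, : ow * p, :].reshape(n, oh, p, ow, p, C)
    return v.max(axis=(2, 4))


def _activate(Z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(Z, 0.0)
    return np.tanh(Z)


def _forward(model: TrainedModel, X: np.ndarray, keep_cache: bool = False):
    """Returns logits (and per-layer caches when training)."""
    spec = model.spec
    caches = []
    if spec.kind == "cnn":
        if X.ndim != 4 or X.shape[1:] != tuple(spec.input_shape):
            raise DataError(
                f"expected input of shape (n, {spec.input_shape}), got {X.shape}")
        a = np.transpose(X, (0, 2, 3, 1))  # to channels-last
    else:
        if X.ndim != 2 or X.shape[1] != spec.input_shape[0]:
            raise DataError(
                f"expected input of shape (n, {spec.input_shape[0]}), got {X.shape}")
        a = X
    flattened = spec.kind == "mlp"
    for layer, w in zip(spec.hidden_layers, model.weights):
        cache = {"in": a}
        if layer.layer_kind == "conv":
            z = _conv_apply(a, w["W"], w["b"])
            cache["z"] = z
            a = _activate(z, layer.activation)
            if layer.pool:
                cache["pre_pool"] = a
                a = _pool_apply(a, layer.pool)
                cache["post_pool"] = a
        else:
            if not flattened:
                cache["pre_flat_shape"] = a.shape
                a = a.reshape(a.shape[0], -1)
                cache["in"] = a
                flattened = True
            z = _dense_apply(a, w["W"], w["b"])
            cache["z"] = z
            a = _activate(z, layer.activation)
        caches.append(cache)
    if not flattened:
        caches.append({"pre_flat_shape": a.shape})
        a = a.reshape(a.shape[0], -1)
    else:
        caches.append({})
    out_w = model.weights[-1]
    caches[-1]["in"] = a
    logits = _dense_apply(a, out_w["W"], out_w["b"])
    return (logits, caches) if keep_cache else logits


def predict_logits(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Forward pass returning raw class logits."""
    return _forward(model, X)


# ---------------------------------------------------------------------------
# backward pass + Adam
# ---------------------------------------------------------------------------

def _act_grad(cache_z: np.ndarray, a: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return (cache_z > 0.0).astype(np.float64)
    return 1.0 - a * a


def _backward(model: TrainedModel, caches: list[dict], dlogits: np.ndarray) -> list[dict]:
    spec = model.spec
    grads: list[dict] = [None] * len(model.weights)
    a_in = caches[-1]["in"]
    out_w = model.weights[-1]
    grads[-1] = {"W": a_in.T @ dlogits, "b": dlogits.sum(axis=0)}
    da = dlogits @ out_w["W"].T
    if "pre_flat_shape" in caches[-1]:
        da = da.reshape(caches[-1]["pre_flat_shape"])
    for i in range(len(spec.hidden_layers) - 1, -1, -1):
        layer = spec.hidden_layers[i]
        w = model.weights[i]
        cache = caches[i]
        if layer.layer_kind == "dense":
            if da.ndim > 2:
                da = da.reshape(da.shape[0], -1)
            a = _activate(cache["z"], layer.activation)
            dz = da * _act_grad(cache["z"], a, layer.activation)
            grads[i] = {"W": cache["in"].T @ dz, "b": dz.sum(axis=0)}
            da = dz @ w["W"].T
            if "pre_flat_shape" in cache:
                da = da.reshape(cache["pre_flat_shape"])
        else:
            if layer.pool:
                da = _pool_backward(da, cache["pre_pool"], cache["post_pool"], layer.pool)
            a = _activate(cache["z"], layer.activation)
            dz = da * _act_grad(cache["z"], a, layer.activation)
            x = cache["in"]
            kh, kw, C, F = w["W"].shape
            n, oh, ow, _ = dz.shape
            dW = np.empty_like(w["W"])
            dx = np.zeros_like(x)
            for dy in range(kh):
                for dx_ in range(kw):
                    patch = x[:, dy:dy + oh, dx_:dx_ + ow, :]  # (n, oh, ow, C)
                    dW[dy, dx_] = np.tensordot(patch, dz, axes=([0, 1, 2], [0, 1, 2]))
                    dx[:, dy:dy + oh, dx_:dx_ + ow, :] += dz @ w["W"][dy, dx_].T
            grads[i] = {"W": dW, "b": dz.sum(axis=(0, 1, 2))}
            da = dx
    return grads


def _pool_backward(dpost: np.ndarray, pre: np.ndarray, post: np.ndarray, p: int) -> np.ndarray:
    n, H, W, C = pre.shape
    oh, ow = H // p, W // p
    dpre = np.zeros_like(pre)
    win = pre[:, : oh * p, : ow * p, :].reshape(n, oh, p, ow, p, C)
    # route gradient to every position attaining the max (ties share it)
    mask = win == post[:, :, None, :, None, :]
    dpre[:, : oh * p, : ow * p, :] = (mask * dpost[:, :, None, :, None, :]).reshape(
        n, oh * p, ow * p, C)
    return dpre


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sgd_adam(model: TrainedModel, data: LabeledDataset, epochs: int,
              lr: float, batch_size: int, seed: int) -> TrainedModel:
    if data.n == 0:
        raise DataError("empty training split")
    out = model.copy()
    rng = np.random.default_rng(seed)
    m_state = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in out.weights]
    v_state = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in out.weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = data.n
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb, yb = data.X[idx], data.y[idx]
            logits, caches = _forward(out, Xb, keep_cache=True)
            probs = _softmax(logits)
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = _backward(out, caches, dlogits)
            t += 1
            corr1 = 1.0 - beta1 ** t
            corr2 = 1.0 - beta2 ** t
            for layer_w, layer_g, ms, vs in zip(out.weights, grads, m_state, v_state):
                for k in layer_w:
                    g = layer_g[k]
                    ms[k] = beta1 * ms[k] + (1 - beta1) * g
                    vs[k] = beta2 * vs[k] + (1 - beta2) * (g * g)
                    layer_w[k] -= lr * (ms[k] / corr1) / (np.sqrt(vs[k] / corr2) + eps)
    return out


def train(model: TrainedModel, data: LabeledDataset, cfg: TrainConfig,
          seed: int | None = None) -> TrainedModel:
    """Train from the model's current weights with mini-batch Adam.

    Deterministic for a fixed (model, data, seed).  Increments the global
    training-call counter.
    """
    s = cfg.seed if seed is None else seed
    out = _sgd_adam(model, data, cfg.epochs, cfg.learning_rate, cfg.batch_size, s)
    out.rng_state["train_seed"] = int(s)
    COUNTERS.train += 1
    return out


def fine_tune(model: TrainedModel, data: LabeledDataset, cfg: TrainConfig,
              seed: int | None = None) -> TrainedModel:
    """Retrain a (pruned) model for ``cfg.fine_tune_epochs`` epochs,
    warm-starting from the surviving weights."""
    s = cfg.seed if seed is None else seed
    if cfg.fine_tune_epochs == 0:
        out = model.copy()
    else:
        out = _sgd_adam(model, data, cfg.fine_tune_epochs, cfg.learning_rate,
                        cfg.batch_size, s)
    COUNTERS.fine_tune += 1
    return out


def validate(model: TrainedModel, data: LabeledDataset) -> float:
    """Fraction of correctly predicted labels on the given split."""
    if data.n == 0:
        raise DataError("empty evaluation split")
    preds = predict_logits(model, data.X).argmax(axis=1)
    COUNTERS.validate += 1
    return float(np.mean(preds == data.y))


# ---------------------------------------------------------------------------
# structured surgery
# ---------------------------------------------------------------------------

def unit_counts(model: TrainedModel) -> list[int]:
    """Current removal-unit count of every hidden layer."""
    return [l.units for l in model.spec.hidden_layers]


def remove_units(model: TrainedModel, layer: int,
                 unit_indices: Iterable[int]) -> TrainedModel:
    """Delete whole nodes/filters from one hidden layer.

    Removes the units' incoming weights and biases and the matching slices
    of the next layer's incoming weights (all flattened positions fed by a
    removed filter at the conv-to-dense boundary).  Surviving weights are
    preserved verbatim.
    """
    spec = model.spec
    if not 0 <= layer < spec.n_hidden:
        raise IndexError(f"no hidden layer {layer}")
    idx = sorted(int(i) for i in unit_indices)
    if len(set(idx)) != len(idx):
        raise IndexError("duplicate unit indices")
    lspec = spec.hidden_layers[layer]
    if idx and (idx[0] < 0 or idx[-1] >= lspec.units):
        raise IndexError("unit index out of range")
    remaining = lspec.units - len(idx)
    if remaining < 1:
        raise StructureError("removal would leave an empty layer")
    keep = np.setdiff1d(np.arange(lspec.units), idx)

    out = model.copy()
    w = out.weights[layer]
    if lspec.layer_kind == "dense":
        w["W"] = w["W"][:, keep]
    else:
        w["W"] = w["W"][..., keep]
    w["b"] = w["b"][keep]

    # downstream slice of the next layer (output layer if last hidden)
    nxt_w = out.weights[layer + 1]
    next_is_conv = (layer + 1 < spec.n_hidden
                    and spec.hidden_layers[layer + 1].layer_kind == "conv")
    if lspec.layer_kind == "dense" or next_is_conv:
        axis = 2 if next_is_conv else 0
        nxt_w["W"] = np.take(nxt_w["W"], keep, axis=axis)
    else:
        # conv feeding a dense layer: drop every flattened (h, w, removed-c)
        oh, ow, c = spec.conv_output_shape()
        mask = np.ones((oh * ow, c), dtype=bool)
        mask[:, idx] = False
        nxt_w["W"] = nxt_w["W"][mask.ravel(), :]

    new_layers = list(spec.hidden_layers)
    new_layers[layer] = replace(lspec, units=remaining)
    out.spec = replace(spec, hidden_layers=tuple(new_layers))
    return out


# ---------------------------------------------------------------------------
# cost counting
# ---------------------------------------------------------------------------

def param_count(model: TrainedModel) -> int:
    """Total number of stored weights and biases."""
    return int(sum(v.size for layer in model.weights for v in layer.values()))


def flop_count(model: TrainedModel) -> int:
    """Forward-pass FLOPs under the package convention.

    Dense layer (fan_in -> units): ``(2*fan_in - 1)*units`` multiply-adds
    plus ``units`` bias additions.  Conv layer: per output position and
    filter, ``2*kh*kw*in_channels - 1`` kernel MACs plus one bias addition.
    Pooling and activations are excluded.  The output layer counts as dense.
    """
    spec = model.spec
    fans = _layer_fan_ins(spec)
    total = 0
    if spec.kind == "cnn":
        c, h, w = spec.input_shape
        for layer in spec.hidden_layers:
            if layer.layer_kind != "conv":
                break
            kh, kw = layer.kernel
            oh, ow = h - kh + 1, w - kw + 1
            total += oh * ow * layer.units * (2 * kh * kw * c - 1 + 1)
            if layer.pool:
                oh, ow = oh // layer.pool, ow // layer.pool
            h, w, c = oh, ow, layer.units
    for i, layer in enumerate(spec.hidden_layers):
        if layer.layer_kind == "dense":
            total += (2 * fans[i] - 1) * layer.units + layer.units
    total += (2 * fans[-1] - 1) * spec.num_classes + spec.num_classes
    return int(total)
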