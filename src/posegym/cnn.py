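"""The per-frame 1-D convolutional classifier.

The reference architecture treats one frame's 78 attributes as a length-78,
single-channel 1-D signal and passes it through four conv/pool blocks, a
flatten, and two fully connected layers:

    input 1x78
    -> Conv1D(32, k=3, valid)  : 76   -> MaxPool(2) : 38
    -> Conv1D(64, k=3, valid)  : 36   -> MaxPool(2) : 18
    -> Conv1D(128, k=3, valid) : 16   -> MaxPool(2) : 8
    -> Conv1D(256, k=3, valid) : 6    -> MaxPool(2) : 3
    -> Flatten : 768 -> Dense(512, relu) -> Dense(10, softmax)

Convolutions are valid (no padding), stride 1; pooling halves the length
with floor division.  The network is implemented in numpy: convolution as
an im2col matrix product, explicit backpropagation, softmax cross-entropy
loss, and Adam updates.  Initialization (He-normal), mini-batch shuffling
and dropout are all driven by one integer seed, so single-threaded runs
are reproducible end to end.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .landmarks import EXERCISE_CLASS_NAMES, ExerciseClass, exercise_class
from .features import FrameFeatures

__all__ = [
    "LayerSpec",
    "ModelConfig",
    "LayerShapes",
    "ClassProbabilities",
    "TrainedModel",
    "ConfigurationError",
    "IntegrityError",
    "StateError",
    "compute_layer_shapes",
    "build_model",
    "train",
    "predict_frame",
    "predict_batch",
    "save_model",
    "load_model",
]

CHECKPOINT_FORMAT_VERSION = 1


class ConfigurationError(ValueError):
    """The layer stack or its hyperparameters are invalid."""


class IntegrityError(RuntimeError):
    """A checkpoint is corrupt or inconsistent with its config."""


class StateError(RuntimeError):
    """Operation requires a trained model."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the stack.  ``maps`` is the channel count for conv
    layers and the unit count for dense layers; ``kernel`` is the conv
    kernel or pool size."""

    kind: str  # conv1d | maxpool1d | flatten | dense
    maps: int = 0
    kernel: int = 0


@dataclass
class ModelConfig:
    """Architecture + training hyperparameters.

    The defaults reproduce the reference stack (78 attributes in, 10 class
    probabilities out).  Optimizer, loss, epochs and batch size are
    standard desk-scale choices and are all overridable.
    """

    input_length: int = 78
    n_classes: int = 10
    conv_channels: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: int = 512
    activation: str = "relu"
    dropout_rate: float = 0.0
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError(f"dropout_rate must be in [0,1): {self.dropout_rate}")
        if self.activation != "relu":
            raise ConfigurationError(f"unsupported activation {self.activation!r}")
        if self.input_length < self.kernel_size:
            raise ConfigurationError(
                f"input_length {self.input_length} smaller than kernel {self.kernel_size}"
            )
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")

    def layers(self) -> list[LayerSpec]:
        stack: list[LayerSpec] = []
        for ch in self.conv_channels:
            stack.append(LayerSpec("conv1d", maps=ch, kernel=self.kernel_size))
            stack.append(LayerSpec("maxpool1d", kernel=self.pool_size))
        stack.append(LayerSpec("flatten"))
        stack.append(LayerSpec("dense", maps=self.dense_units))
        stack.append(LayerSpec("dense", maps=self.n_classes))
        return stack


@dataclass(frozen=True)
class LayerShapes:
    """Output length after each conv/pool layer, plus the flatten width."""

    lengths: tuple[int, ...]
    flatten_width: int


def compute_layer_shapes(config: ModelConfig) -> LayerShapes:
    """Propagate the 1-D signal length through the stack.

    Valid convolution maps length L to L - k + 1; pooling maps L to
    floor(L / pool).  Raises :class:`ConfigurationError` if any
    intermediate length drops below the next kernel.
    """
    length = config.input_length
    channels = 1
    lengths: list[int] = []
    for spec in config.layers():
        if spec.kind == "conv1d":
            if length < spec.kernel:
                raise ConfigurationError(
                    f"length {length} smaller than conv kernel {spec.kernel}"
                )
            length = length - spec.kernel + 1
            channels = spec.maps
            lengths.append(length)
        elif spec.kind == "maxpool1d":
            if length < spec.kernel:
                raise ConfigurationError(
                    f"length {length} smaller than pool size {spec.kernel}"
                )
            length = length // spec.kernel
            lengths.append(length)
        elif spec.kind == "flatten":
            break
    return LayerShapes(tuple(lengths), flatten_width=length * channels)


@dataclass
class ClassProbabilities:
    """Softmax output for one frame: non-negative, sums to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if np.any(self.probs < 0) or abs(float(self.probs.sum()) - 1.0) > 1e-6:
            raise ValueError("probs must be non-negative and sum to 1")

    @property
    def predicted_index(self) -> int:
        return int(np.argmax(self.probs))


# ---------------------------------------------------------------------------
# parameter store and forward/backward passes
# ---------------------------------------------------------------------------


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-normal initialization; biases zero.  Conv weights are stored
    flattened as (in_channels * kernel, out_channels) for the im2col
    product."""
    params: dict[str, np.ndarray] = {}
    in_ch = 1
    for i, ch in enumerate(config.conv_channels):
        fan_in = in_ch * config.kernel_size
        params[f"conv{i}_W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(fan_in, ch)
        ).astype(np.float32)
        params[f"conv{i}_b"] = np.zeros(ch, dtype=np.float32)
        in_ch = ch
    flat = compute_layer_shapes(config).flatten_width
    params["dense0_W"] = rng.normal(
        0.0, np.sqrt(2.0 / flat), size=(flat, config.dense_units)
    ).astype(np.float32)
    params["dense0_b"] = np.zeros(config.dense_units, dtype=np.float32)
    params["dense1_W"] = rng.normal(
        0.0, np.sqrt(2.0 / config.dense_units),
        size=(config.dense_units, config.n_classes),
    ).astype(np.float32)
    params["dense1_b"] = np.zeros(config.n_classes, dtype=np.float32)
    return params


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, C*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, Lo, C, k)
    B, Lo, C, _ = win.shape
    return win.reshape(B, Lo, C * k)


def _forward(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    X: np.ndarray,
    *,
    train_mode: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, list]:
    """Forward pass.  Returns softmax probabilities (B, n_classes) and the
    cache needed for backpropagation."""
    B = X.shape[0]
    x = X.reshape(B, config.input_length, 1).astype(np.float32)
    cache: list = []
    for i in range(len(config.conv_channels)):
        W, b = params[f"conv{i}_W"], params[f"conv{i}_b"]
        k = config.kernel_size
        cols = _im2col(x, k)
        z = cols @ W + b
        a = np.maximum(z, 0.0)
        # pool: truncate to a multiple of pool_size, take block max
        p = config.pool_size
        Lp = a.shape[1] // p
        ar = a[:, : Lp * p, :].reshape(B, Lp, p, a.shape[2])
        idx = ar.argmax(axis=2)
        pooled = np.take_along_axis(ar, idx[:, :, None, :], axis=2)[:, :, 0, :]
        cache.append(("conv", x.shape, cols, z, a.shape, idx))
        x = pooled
    flat = x.reshape(B, -1)
    W0, b0 = params["dense0_W"], params["dense0_b"]
    z0 = flat @ W0 + b0
    a0 = np.maximum(z0, 0.0)
    drop_mask = None
    if train_mode and config.dropout_rate > 0.0:
        keep = 1.0 - config.dropout_rate
        drop_mask = (rng.random(a0.shape) < keep).astype(np.float32) / keep
        a0 = a0 * drop_mask
    W1, b1 = params["dense1_W"], params["dense1_b"]
    z1 = a0 @ W1 + b1
    z1 = z1 - z1.max(axis=1, keepdims=True)
    e = np.exp(z1)
    probs = e / e.sum(axis=1, keepdims=True)
    cache.append(("head", x.shape, flat, z0, a0, drop_mask))
    return probs, cache


def _backward(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    probs: np.ndarray,
    y_onehot: np.ndarray,
    cache: list,
) -> dict[str, np.ndarray]:
    """Gradients of mean softmax cross-entropy w.r.t. every parameter."""
    B = probs.shape[0]
    grads: dict[str, np.ndarray] = {}
    kind, pooled_shape, flat, z0, a0, drop_mask = cache[-1]
    assert kind == "head"
    dz1 = (probs - y_onehot).astype(np.float32) / B
    grads["dense1_W"] = a0.T @ dz1
    grads["dense1_b"] = dz1.sum(axis=0)
    da0 = dz1 @ params["dense1_W"].T
    if drop_mask is not None:
        da0 = da0 * drop_mask
    dz0 = da0 * (z0 > 0.0)
    grads["dense0_W"] = flat.T @ dz0
    grads["dense0_b"] = dz0.sum(axis=0)
    dx = (dz0 @ params["dense0_W"].T).reshape(pooled_shape)

    p = config.pool_size
    k = config.kernel_size
    for i in range(len(config.conv_channels) - 1, -1, -1):
        kind, x_shape, cols, z, a_shape, idx = cache[i]
        assert kind == "conv"
        # un-pool: route gradient to the argmax positions
        _, Lo, M = a_shape
        Lp = Lo // p
        dar = np.zeros((B, Lp, p, M), dtype=np.float32)
        np.put_along_axis(dar, idx[:, :, None, :], dx[:, :, None, :], axis=2)
        da = np.zeros((B, Lo, M), dtype=np.float32)
        da[:, : Lp * p, :] = dar.reshape(B, Lp * p, M)
        dz = da * (z > 0.0)
        W = params[f"conv{i}_W"]
        Ck = W.shape[0]
        grads[f"conv{i}_W"] = cols.reshape(-1, Ck).T @ dz.reshape(-1, M)
        grads[f"conv{i}_b"] = dz.sum(axis=(0, 1))
        # fold column gradients back onto the input signal
        dcols = (dz @ W.T).reshape(B, Lo, x_shape[2], k)
        dx = np.zeros(x_shape, dtype=np.float32)
        for j in range(k):
            dx[:, j : j + Lo, :] += dcols[:, :, :, j]
    return grads


@dataclass
class TrainedModel:
    """Model parameters plus the config and class registry they were built
    with.  ``training_log`` holds one record per epoch."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    class_names: tuple[str, ...] = EXERCISE_CLASS_NAMES
    training_log: list[dict] = field(default_factory=list)
    trained: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise StateError("model has not been trained")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.input_length:
            raise ConfigurationError(
                f"feature vectors of length {X.shape[1]}, model expects "
                f"{self.config.input_length}"
            )
        probs, _ = _forward(self.params, self.config, X)
        return probs.astype(np.float64)


def build_model(config: ModelConfig) -> TrainedModel:
    """Construct an untrained model with seeded He-normal weights whose
    shapes match :func:`compute_layer_shapes`."""
    rng = np.random.default_rng(config.seed)
    return TrainedModel(config=config, params=_init_params(config, rng))


def _as_matrix(
    features: Sequence, input_length: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Flatten (FrameFeatures | vector, ExerciseClass[, group]) pairs into
    X, y arrays; validates vector lengths."""
    X_rows, y_rows, groups = [], [], []
    for item in features:
        f, cls = item[0], item[1]
        grp = item[2] if len(item) > 2 else ""
        vec = f.vector if isinstance(f, FrameFeatures) else np.asarray(f, dtype=np.float64)
        if vec.shape != (input_length,):
            raise ConfigurationError(
                f"feature vector of length {vec.size}, expected {input_length}"
            )
        X_rows.append(vec)
        y_rows.append(cls.index if isinstance(cls, ExerciseClass) else int(cls))
        groups.append(str(grp))
    return (
        np.asarray(X_rows, dtype=np.float32),
        np.asarray(y_rows, dtype=np.int64),
        groups,
    )


def train(
    model: TrainedModel,
    features: Sequence,
    *,
    epochs: Optional[int] = None,
    seed: Optional[int] = None,
    validation_features: Optional[Sequence] = None,
) -> TrainedModel:
    """Train with Adam on softmax cross-entropy.

    ``features`` is a sequence of ``(FrameFeatures | vector, ExerciseClass)``
    pairs; every frame carries its sequence's label.  Splitting into train
    and validation sets is the caller's job and must be done at the
    sequence level (never per frame) to avoid leakage; a pre-split
    ``validation_features`` is evaluated after each epoch.

    Every class the model's output head covers must appear in the training
    data; missing classes (and single-class data in particular) are
    configuration errors.
    """
    cfg = model.config
    X, y, _ = _as_matrix(features, cfg.input_length)
    present = set(np.unique(y).tolist())
    missing = [c for c in range(cfg.n_classes) if c not in present]
    if len(present) < 2 or missing:
        names = [
            model.class_names[c] if c < len(model.class_names) else str(c)
            for c in missing
        ]
        raise ConfigurationError(
            f"training data covers {len(present)} of {cfg.n_classes} classes; "
            f"missing: {names}"
        )
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    Xval = yval = None
    if validation_features is not None:
        Xval, yval, _ = _as_matrix(validation_features, cfg.input_length)

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate
    t = 0
    n = X.shape[0]
    eye = np.eye(cfg.n_classes, dtype=np.float32)

    for epoch in range(epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            probs, cache = _forward(
                model.params, cfg, xb, train_mode=True, rng=rng
            )
            total_loss += float(
                -np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)).sum()
            )
            correct += int((probs.argmax(axis=1) == yb).sum())
            grads = _backward(model.params, cfg, probs, eye[yb], cache)
            t += 1
            for kname, g in grads.items():
                m[kname] = beta1 * m[kname] + (1 - beta1) * g
                v[kname] = beta2 * v[kname] + (1 - beta2) * g * g
                mhat = m[kname] / (1 - beta1**t)
                vhat = v[kname] / (1 - beta2**t)
                model.params[kname] -= lr * mhat / (np.sqrt(vhat) + eps)
        record = {
            "epoch": epoch,
            "loss": total_loss / n,
            "accuracy": correct / n,
        }
        if Xval is not None:
            model.trained = True
            vp = model.predict_proba(Xval)
            record["val_accuracy"] = float((vp.argmax(axis=1) == yval).mean())
        model.training_log.append(record)
    model.trained = True
    return model


def predict_frame(model: TrainedModel, f: FrameFeatures | np.ndarray) -> ClassProbabilities:
    """Class-probability vector for one frame (softmax output)."""
    vec = f.vector if isinstance(f, FrameFeatures) else np.asarray(f)
    probs = model.predict_proba(vec)[0]
    return ClassProbabilities(probs / probs.sum())


def predict_batch(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Probabilities for a batch of frames, order preserved: (N, n_classes)."""
    return model.predict_proba(X)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Write a checkpoint directory: ``config.json`` (full config, class
    registry, format version, training log) + ``weights.npz``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["conv_channels"] = list(model.config.conv_channels)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": cfg,
        "class_names": list(model.class_names),
        "trained": model.trained,
        "training_log": model.training_log,
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "weights.npz", **model.params)
    return path


def load_model(path: str | Path) -> TrainedModel:
    """Load a checkpoint; verifies weight shapes against the config and the
    class registry against the package's."""
    path = Path(path)
    try:
        meta = json.loads((path / "config.json").read_text())
        cfg_dict = dict(meta["config"])
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        config = ModelConfig(**cfg_dict)
        with np.load(path / "weights.npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
    except (OSError, KeyError, ValueError, EOFError, zipfile.BadZipFile,
            json.JSONDecodeError) as exc:
        raise IntegrityError(f"cannot load checkpoint at {path}: {exc}") from exc
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise IntegrityError(f"unsupported checkpoint version {meta.get('format_version')}")
    class_names = tuple(meta["class_names"])
    if len(class_names) != config.n_classes:
        raise IntegrityError("class registry size does not match config")
    expected = _init_params(config, np.random.default_rng(0))
    if set(expected) != set(params):
        raise IntegrityError(
            f"weight keys {sorted(params)} do not match config {sorted(expected)}"
        )
    for k in expected:
        if expected[k].shape != params[k].shape:
            raise IntegrityError(
                f"weight {k} has shape {params[k].shape}, config implies {expected[k].shape}"
            )
    return TrainedModel(
        config=config,
        params=params,
        class_names=class_names,
        training_log=list(meta.get("training_log", [])),
        trained=bool(meta.get("trained", False)),
    )
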