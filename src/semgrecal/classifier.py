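"""Compact convolutional classifier for 5x5x12 feature grids.

Architecture: one valid (no-padding) convolutional layer — a 4x4 filter over
the 5x5 grid, summing across the 12 input channels like the RGB planes of an
image, giving 2x2 spatial maps — followed by two fully connected hidden
layers with ReLU and inverted dropout, and a softmax output over the M
movement classes. Training is plain mini-batch gradient descent on the
softmax cross-entropy loss, with hand-written backpropagation; the analytic
gradients are exposed through :func:`loss_and_grads` so they can be verified
against finite differences.

The same machinery supports from-scratch training and warm-started
fine-tuning (:func:`fine_tune`), which continues optimization from the
current weights for fewer epochs — retaining the memory of earlier sessions
while adapting to new data. For ablation studies the convolutional layer can
be replaced by a fully connected layer of equal output width
(``use_conv=False``), and dropout disabled via ``dropout_rate=0``.

All randomness (initialization, batch shuffling, dropout masks) flows from
explicit integer seeds, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, DivergenceError, ParameterError

__all__ = ["ModelConfig", "TrainConfig", "ModelState", "build_model",
           "conv_forward", "train", "fine_tune", "predict_proba",
           "loss_and_grads", "save_model", "load_model"]


@dataclass
class ModelConfig:
    n_classes: int
    grid_size: int = 5
    n_channels: int = 12
    conv_filter: int = 4
    n_filters: int = 64
    fc_neurons: int = 800
    dropout_rate: float = 0.5
    use_conv: bool = True

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.conv_filter > self.grid_size:
            raise ConfigurationError(
                f"conv_filter {self.conv_filter} does not fit grid {self.grid_size}")

    @property
    def conv_out(self) -> int:
        """Spatial side of the valid-convolution output (grid - filter + 1)."""
        return self.grid_size - self.conv_filter + 1

    @property
    def conv_features(self) -> int:
        return self.conv_out * self.conv_out * self.n_filters


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 0.01
    seed: int = 0
    mode: str = "from_scratch"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigurationError("TrainConfig values must be positive")
        if self.mode not in ("from_scratch", "fine_tune"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


@dataclass
class ModelState:
    """All weights plus the training step counter and the init seed."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    step: int = 0
    seed: int = 0

    def copy(self) -> "ModelState":
        return ModelState(config=self.config,
                          params={k: v.copy() for k, v in self.params.items()},
                          step=self.step, seed=self.seed)


def build_model(config: ModelConfig, seed: int = 0) -> ModelState:
    """He-initialized network; identical seeds give identical weights."""
    rng = np.random.default_rng(seed)
    k, c, f = config.conv_filter, config.n_channels, config.n_filters
    h, m = config.fc_neurons, config.n_classes
    d_in = config.grid_size ** 2 * c

    def he(shape, fan_in):
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

    params: dict[str, np.ndarray] = {}
    if config.use_conv:
        params["W1"] = he((f, k, k, c), k * k * c)
        params["b1"] = np.zeros(f)
    else:
        # ablation: conv layer replaced by a dense layer of equal output width
        params["W1"] = he((d_in, config.conv_features), d_in)
        params["b1"] = np.zeros(config.conv_features)
    params["W2"] = he((config.conv_features, h), config.conv_features)
    params["b2"] = np.zeros(h)
    params["W3"] = he((h, h), h)
    params["b3"] = np.zeros(h)
    params["W4"] = he((h, m), h)
    params["b4"] = np.zeros(m)
    return ModelState(config=config, params=params, step=0, seed=seed)


def conv_forward(grids: np.ndarray, filters: np.ndarray,
                 bias: np.ndarray | None = None) -> np.ndarray:
    """Valid cross-correlation of N x g x g x C grids with F x k x k x C filters.

    Each filter position computes a dot product over its k x k x C receptive
    field, summing across input channels; output is N x o x o x F with
    o = g - k + 1.
    """
    grids = np.asarray(grids, dtype=np.float64)
    filters = np.asarray(filters, dtype=np.float64)
    k = filters.shape[1]
    if k > grids.shape[1] or filters.shape[3] != grids.shape[3]:
        raise ParameterError("filter does not fit the input grid")
    windows = np.lib.stride_tricks.sliding_window_view(grids, (k, k), axis=(1, 2))
    out = np.einsum("nijcab,fabc->nijf", windows, filters)
    if bias is not None:
        out = out + bias
    return out


def _forward(model: ModelState, x: np.ndarray, dropout_rng=None):
    """Full forward pass; returns probabilities and the cache for backprop.

    ``dropout_rng`` enables inverted dropout (training); ``None`` disables it
    (inference / gradient checking without dropout).
    """
    cfg = model.config
    p = model.params
    n = x.shape[0]
    cache: dict = {"x": x}
    if cfg.use_conv:
        k = cfg.conv_filter
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        s1 = np.einsum("nijcab,fabc->nijf", windows, p["W1"]) + p["b1"]
        cache["windows"] = windows
    else:
        flat = x.reshape(n, -1)
        s1 = flat @ p["W1"] + p["b1"]
        cache["flat"] = flat
    a1 = np.maximum(s1, 0.0)
    z = a1.reshape(n, -1)
    cache["s1"], cache["z"] = s1, z

    keep = 1.0 - cfg.dropout_rate

    def dropout_mask(shape):
        if dropout_rng is None or cfg.dropout_rate == 0.0:
            return None
        return (dropout_rng.random(shape) < keep) / keep

    s2 = z @ p["W2"] + p["b2"]
    a2 = np.maximum(s2, 0.0)
    m2 = dropout_mask(a2.shape)
    a2d = a2 if m2 is None else a2 * m2
    s3 = a2d @ p["W3"] + p["b3"]
    a3 = np.maximum(s3, 0.0)
    m3 = dropout_mask(a3.shape)
    a3d = a3 if m3 is None else a3 * m3
    s4 = a3d @ p["W4"] + p["b4"]
    s4 = s4 - s4.max(axis=1, keepdims=True)
    exp = np.exp(s4)
    probs = exp / exp.sum(axis=1, keepdims=True)
    cache.update(s2=s2, a2d=a2d, m2=m2, s3=s3, a3d=a3d, m3=m3, probs=probs)
    return probs, cache


def _backward(model: ModelState, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
    cfg = model.config
    p = model.params
    n = len(y)
    probs = cache["probs"]
    ds4 = probs.copy()
    ds4[np.arange(n), y] -= 1.0
    ds4 /= n
    grads: dict[str, np.ndarray] = {}
    grads["W4"] = cache["a3d"].T @ ds4
    grads["b4"] = ds4.sum(axis=0)
    da3d = ds4 @ p["W4"].T
    da3 = da3d if cache["m3"] is None else da3d * cache["m3"]
    ds3 = da3 * (cache["s3"] > 0)
    grads["W3"] = cache["a2d"].T @ ds3
    grads["b3"] = ds3.sum(axis=0)
    da2d = ds3 @ p["W3"].T
    da2 = da2d if cache["m2"] is None else da2d * cache["m2"]
    ds2 = da2 * (cache["s2"] > 0)
    grads["W2"] = cache["z"].T @ ds2
    grads["b2"] = ds2.sum(axis=0)
    dz = ds2 @ p["W2"].T
    ds1 = dz.reshape(cache["s1"].shape) * (cache["s1"] > 0)
    if cfg.use_conv:
        grads["W1"] = np.einsum("nijcab,nijf->fabc", cache["windows"], ds1)
        grads["b1"] = ds1.sum(axis=(0, 1, 2))
    else:
        grads["W1"] = cache["flat"].T @ ds1
        grads["b1"] = ds1.sum(axis=0)
    return grads


def loss_and_grads(model: ModelState, x: np.ndarray, y: np.ndarray,
                   dropout_rng=None) -> tuple[float, dict[str, np.ndarray]]:
    """Mean softmax cross-entropy and its analytic parameter gradients."""
    probs, cache = _forward(model, x, dropout_rng)
    n = len(y)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-300)))
    return loss, _backward(model, cache, y)


def train(model: ModelState, grids: np.ndarray, labels: np.ndarray,
          config: TrainConfig) -> ModelState:
    """Mini-batch SGD on cross-entropy; returns a new trained ModelState.

    The input model is left untouched. Dropout masks are resampled per batch
    (training only); inference uses no dropout and needs no rescaling since
    dropout is inverted.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= model.config.n_classes:
        raise ParameterError(
            f"labels must lie in [0, {model.config.n_classes}), "
            f"got range [{labels.min()}, {labels.max()}]")
    out = model.copy()
    rng = np.random.default_rng(config.seed)
    n = len(labels)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = grids[idx], labels[idx]
            probs, cache = _forward(out, xb, dropout_rng=rng)
            loss = float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-300)))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at step {out.step}; "
                    f"learning rate {config.learning_rate} is likely too large")
            grads = _backward(out, cache, yb)
            for key, g in grads.items():
                out.params[key] -= config.learning_rate * g
            out.step += 1
    return out


def fine_tune(model: ModelState, grids: np.ndarray, labels: np.ndarray,
              config: TrainConfig | None = None) -> ModelState:
    """Warm-start continuation of training from the current weights.

    Defaults to fewer epochs (15) than from-scratch training: the pretrained
    network already provides a good initial condition, and the fine-tune only
    tracks session-to-session drift.
    """
    if model.step == 0:
        raise ParameterError("fine_tune requires a previously trained model")
    if config is None:
        config = TrainConfig(epochs=15, mode="fine_tune")
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and labels.max() >= model.config.n_classes:
        raise ParameterError(
            f"label {labels.max()} outside the model's {model.config.n_classes} classes")
    return train(model, grids, labels, config)


def predict_proba(model: ModelState, grids: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic inference: class-probability rows P(i, .) and labels L^i.

    Probabilities sum to 1 per segment; the label is the argmax class.
    """
    probs, _ = _forward(model, np.asarray(grids, dtype=np.float64), dropout_rng=None)
    return probs, probs.argmax(axis=1)


def save_model(model: ModelState, path) -> None:
    """Single-file checkpoint with the config embedded; bit-exact round-trip."""
    meta = json.dumps({"config": asdict(model.config), "step": model.step,
                       "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> ModelState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return ModelState(config=ModelConfig(**meta["config"]), params=params,
                      step=meta["step"], seed=meta["seed"])
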