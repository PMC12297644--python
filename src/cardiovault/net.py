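"""Small trainable neural classifier for tabular clinical features.

Architecture (configurable): optional 1-D convolution over the ordered
13-feature vector (stride 1, same padding) with batch normalization and
ReLU, then a 100-unit dense ReLU layer, inverted dropout, and a 2-way
softmax head.  Training is explicit mini-batch SGD with classical momentum
on the cross-entropy loss; all gradients are hand-derived (no autodiff), so
they can be checked against finite differences.

Features are standardized with a scaler fitted on the training split and
stored with the model.  Optional inverse-frequency class weighting
counteracts the class imbalance typical of cardiac cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "NetworkConfig",
    "ModelParams",
    "TrainReport",
    "baseline_config",
    "tuned_config",
    "build_model",
    "forward",
    "loss_and_grads",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_BN_EPS = 1e-5


@dataclass
class NetworkConfig:
    """Classifier configuration.

    Defaults follow the baseline parameter setting (learning rate 0.1,
    32 epochs, dropout 0.243, batch size 8) with a 100-unit dense layer and
    momentum 0.9.
    """

    input_dim: int = 13
    use_conv: bool = False
    conv_filters: int = 16
    conv_kernel: int = 3
    use_batchnorm: bool = True  # only meaningful when use_conv
    dense_units: int = 100
    dropout_rate: float = 0.243
    n_classes: int = 2
    learning_rate: float = 0.1
    momentum: float = 0.9
    epochs: int = 32
    batch_size: int = 8
    class_weighting: str = "none"  # or "inverse_frequency"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.n_classes != 2:
            raise ValueError("only binary classification is supported")
        if self.class_weighting not in ("none", "inverse_frequency"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


def baseline_config(**overrides) -> NetworkConfig:
    """The baseline training setting: lr 0.1, 32 epochs, dropout 0.243,
    batch size 8."""
    return NetworkConfig(**overrides)


def tuned_config(**overrides) -> NetworkConfig:
    """An example optimizer-found setting: lr 1e-4, momentum 0.9, 30 epochs,
    dropout 0.2."""
    kw = dict(learning_rate=1e-4, momentum=0.9, epochs=30, dropout_rate=0.2)
    kw.update(overrides)
    return NetworkConfig(**kw)


@dataclass
class ModelParams:
    """Weights plus the stored feature scaler and config."""

    arrays: Dict[str, np.ndarray]
    config: NetworkConfig
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None

    def n_parameters(self) -> int:
        # batch-norm running moments are buffers, not trainable parameters
        return sum(v.size for k, v in self.arrays.items()
                   if not k.startswith("bn_running"))

    def copy(self) -> "ModelParams":
        return ModelParams(
            arrays={k: v.copy() for k, v in self.arrays.items()},
            config=self.config,
            scaler_mean=None if self.scaler_mean is None else self.scaler_mean.copy(),
            scaler_std=None if self.scaler_std is None else self.scaler_std.copy(),
        )


@dataclass
class TrainReport:
    train_loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    config: NetworkConfig | None = None


def build_model(config: NetworkConfig) -> ModelParams:
    """He-style seeded initialization; batch-norm moments start at (0, 1)."""
    rng = np.random.default_rng(config.seed)
    arrays: Dict[str, np.ndarray] = {}
    flat_dim = config.input_dim
    if config.use_conv:
        fan_in = config.conv_kernel
        arrays["conv_w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (config.conv_kernel, config.conv_filters)
        )
        if config.use_batchnorm:
            # batch-norm's beta makes a conv bias redundant (its gradient is
            # identically zero), so the bias exists only without batch-norm
            arrays["bn_gamma"] = np.ones(config.conv_filters)
            arrays["bn_beta"] = np.zeros(config.conv_filters)
            arrays["bn_running_mean"] = np.zeros(config.conv_filters)
            arrays["bn_running_var"] = np.ones(config.conv_filters)
        else:
            arrays["conv_b"] = np.zeros(config.conv_filters)
        flat_dim = config.input_dim * config.conv_filters
    arrays["w1"] = rng.normal(0.0, np.sqrt(2.0 / flat_dim),
                              (flat_dim, config.dense_units))
    arrays["b1"] = np.zeros(config.dense_units)
    arrays["w2"] = rng.normal(0.0, np.sqrt(2.0 / config.dense_units),
                              (config.dense_units, config.n_classes))
    arrays["b2"] = np.zeros(config.n_classes)
    return ModelParams(arrays=arrays, config=config)


def _standardize(params: ModelParams, X: np.ndarray) -> np.ndarray:
    if params.scaler_mean is None:
        return X
    return (X - params.scaler_mean) / params.scaler_std


def _conv1d_same(
    X: np.ndarray, w: np.ndarray, b: np.ndarray | None
) -> Tuple[np.ndarray, np.ndarray]:
    """Single-input-channel 1-D convolution with same padding.

    X: (n, L); w: (kernel, filters); returns (out (n, L, filters),
    windows (n, L, kernel)) with windows cached for the backward pass.
    """
    n, L = X.shape
    kernel = w.shape[0]
    pad = kernel // 2
    Xp = np.pad(X, ((0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(Xp, kernel, axis=1)[:, :L, :]
    out = windows @ w
    if b is not None:
        out = out + b
    return out, windows


def _forward_pass(
    params: ModelParams,
    X: np.ndarray,
    training: bool,
    rng: np.random.Generator | None,
) -> Tuple[np.ndarray, dict]:
    """Forward through the configured stack; returns (probs, cache)."""
    cfg = params.config
    a = params.arrays
    cache: dict = {"X": X}
    h = X
    if cfg.use_conv:
        conv, windows = _conv1d_same(h, a["conv_w"], a.get("conv_b"))
        cache["windows"] = windows
        if cfg.use_batchnorm:
            if training:
                mu = conv.mean(axis=(0, 1))
                var = conv.var(axis=(0, 1))
                # exponential running moments (momentum 0.9)
                a["bn_running_mean"][:] = 0.9 * a["bn_running_mean"] + 0.1 * mu
                a["bn_running_var"][:] = 0.9 * a["bn_running_var"] + 0.1 * var
            else:
                mu = a["bn_running_mean"]
                var = a["bn_running_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (conv - mu) * inv_std
            bn = a["bn_gamma"] * xhat + a["bn_beta"]
            cache.update(xhat=xhat, inv_std=inv_std, bn_training=training)
            act_in = bn
        else:
            act_in = conv
        relu_c = np.maximum(act_in, 0.0)
        cache["relu_c_mask"] = act_in > 0
        h = relu_c.reshape(X.shape[0], -1)
    z1 = h @ a["w1"] + a["b1"]
    h1 = np.maximum(z1, 0.0)
    cache.update(flat=h, relu1_mask=z1 > 0)
    if training and cfg.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")
        keep = 1.0 - cfg.dropout_rate
        mask = (rng.random(h1.shape) < keep) / keep  # inverted dropout
        h1 = h1 * mask
        cache["dropout_mask"] = mask
    cache["h1"] = h1
    logits = h1 @ a["w2"] + a["b2"]
    logits = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    probs = exp / exp.sum(axis=1, keepdims=True)
    cache["probs"] = probs
    return probs, cache


def forward(
    params: ModelParams,
    X: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class probabilities, rows summing to 1.  Dropout (and batch
    statistics) apply only when ``training``; inference uses running
    moments and no dropout.  Raises on NaN inputs, naming the row."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.config.input_dim:
        raise ValueError(
            f"expected (n, {params.config.input_dim}) features, got {X.shape}"
        )
    bad = np.where(~np.isfinite(X).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite feature values in row {int(bad[0])}")
    Xs = _standardize(params, X)
    probs, _ = _forward_pass(params, Xs, training, rng)
    return probs


def loss_and_grads(
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray | None = None,
    training: bool = True,
    rng_seed: int | None = None,
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Weighted cross-entropy and analytic gradients of every trainable
    tensor.  ``rng_seed`` fixes the dropout mask so the loss is a
    deterministic function of the parameters (finite-difference checkable).

    X must already be standardized (the training loop standardizes once).
    """
    cfg = params.config
    a = params.arrays
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None
    probs, cache = _forward_pass(params, X, training, rng)
    n = X.shape[0]
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=float)
    wsum = w.sum()
    eps = 1e-12
    loss = float(-(w * np.log(probs[np.arange(n), y] + eps)).sum() / wsum)

    grads: Dict[str, np.ndarray] = {}
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    h1 = cache["h1"]
    grads["w2"] = h1.T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    dh1 = dlogits @ a["w2"].T
    if training and cfg.dropout_rate > 0.0:
        dh1 = dh1 * cache["dropout_mask"]
    dz1 = dh1 * cache["relu1_mask"]
    flat = cache["flat"]
    grads["w1"] = flat.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    if cfg.use_conv:
        dflat = dz1 @ a["w1"].T
        L = cfg.input_dim
        dact = dflat.reshape(n, L, cfg.conv_filters) * cache["relu_c_mask"]
        if cfg.use_batchnorm:
            xhat, inv_std = cache["xhat"], cache["inv_std"]
            grads["bn_gamma"] = (dact * xhat).sum(axis=(0, 1))
            grads["bn_beta"] = dact.sum(axis=(0, 1))
            if cache["bn_training"]:
                m = n * L
                dxhat = dact * a["bn_gamma"]
                dconv = (inv_std / m) * (
                    m * dxhat
                    - dxhat.sum(axis=(0, 1))
                    - xhat * (dxhat * xhat).sum(axis=(0, 1))
                )
            else:
                dconv = dact * a["bn_gamma"] * inv_std
        else:
            dconv = dact
        windows = cache["windows"]  # (n, L, kernel)
        grads["conv_w"] = np.einsum("nlk,nlf->kf", windows, dconv)
        if "conv_b" in a:
            grads["conv_b"] = dconv.sum(axis=(0, 1))
    return loss, grads


def _class_weights(y: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "none":
        return np.ones(y.shape[0])
    counts = np.bincount(y, minlength=2).astype(float)
    w_class = y.shape[0] / (2.0 * counts)  # inverse frequency, mean ~1
    return w_class[y]


def _eval_metrics(params: ModelParams, Xs: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    probs, _ = _forward_pass(params, Xs, training=False, rng=None)
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(len(y)), y] + eps).mean())
    labels = (probs[:, 1] > probs[:, 0]).astype(int)
    return loss, float((labels == y).mean())


def train(
    config: NetworkConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> Tuple[ModelParams, TrainReport]:
    """Mini-batch SGD with classical momentum on the cross-entropy.

    The feature scaler is fitted here and stored in the returned model.
    Per-epoch entries record full-set loss/accuracy in inference mode.  If
    an epoch leaves any parameter non-finite (possible at aggressive
    learning rates) the epoch is rolled back and training stops early,
    repeating the last finite metrics for the remaining epochs so report
    lengths stay equal to ``epochs``.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if config.batch_size > X_train.shape[0]:
        raise ValueError("batch_size exceeds the training-set size")

    params = build_model(config)
    params.scaler_mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    params.scaler_std = np.where(std > 0, std, 1.0)
    Xs = _standardize(params, X_train)
    Xv = yv = None
    if X_val is not None and y_val is not None and len(y_val):
        Xv = _standardize(params, np.asarray(X_val, dtype=float))
        yv = np.asarray(y_val, dtype=int)

    weights = _class_weights(y_train, config.class_weighting)
    rng = np.random.default_rng(config.seed + 1)
    velocity = {k: np.zeros_like(v) for k, v in params.arrays.items()
                if not k.startswith("bn_running")}
    report = TrainReport(config=config)
    n = Xs.shape[0]
    stopped = False
    for epoch in range(config.epochs):
        if not stopped and config.learning_rate > 0.0:
            snapshot = params.copy()
            perm = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = perm[start:start + config.batch_size]
                seed = int(rng.integers(0, 2**31))
                _, grads = loss_and_grads(
                    params, Xs[idx], y_train[idx], weights[idx],
                    training=True, rng_seed=seed,
                )
                for k, g in grads.items():
                    velocity[k] = config.momentum * velocity[k] - config.learning_rate * g
                    params.arrays[k] += velocity[k]
            if not all(np.isfinite(v).all() for v in params.arrays.values()):
                params = snapshot  # roll back the diverged epoch
                stopped = True
        tr_loss, tr_acc = _eval_metrics(params, Xs, y_train)
        report.train_loss.append(tr_loss)
        report.train_accuracy.append(tr_acc)
        if Xv is not None:
            v_loss, v_acc = _eval_metrics(params, Xv, yv)
            report.val_loss.append(v_loss)
            report.val_accuracy.append(v_acc)
    return params, report


def predict(params: ModelParams, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Labels (argmax; exact ties break toward class 0) and probabilities."""
    probs = forward(params, X, training=False)
    labels = (probs[:, 1] > probs[:, 0]).astype(int)
    return labels, probs


def save_model(params: ModelParams, path: str) -> None:
    """Single NPZ archive with the config embedded as JSON."""
    payload = {k: v for k, v in params.arrays.items()}
    if params.scaler_mean is not None:
        payload["scaler_mean"] = params.scaler_mean
        payload["scaler_std"] = params.scaler_std
    payload["config_json"] = np.array(json.dumps(asdict(params.config)))
    np.savez(path, **payload)


def load_model(path: str) -> ModelParams:
    with np.load(path, allow_pickle=False) as data:
        config = NetworkConfig(**json.loads(str(data["config_json"])))
        arrays = {k: data[k] for k in data.files
                  if k not in ("config_json", "scaler_mean", "scaler_std")}
        mean = data["scaler_mean"] if "scaler_mean" in data.files else None
        std = data["scaler_std"] if "scaler_std" in data.files else None
    return ModelParams(arrays=arrays, config=config,
                       scaler_mean=mean, scaler_std=std)
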