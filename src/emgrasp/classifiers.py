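"""Classifiers: the compact CNN for PCA-grid features and the SVM
baseline for time-domain/AR features.

The CNN is deliberately small: one convolutional layer of 400 filters
of size 4x4 (valid padding, stride 1) over the 5x5xC PC grid, a
rectified-linear activation, one fully connected layer of 400 units
with dropout 0.5 during training, and a K-way softmax output trained
with cross-entropy. Optimization is plain mini-batch stochastic
gradient descent (learning rate 0.001, momentum 0.9, batch 32, 100
epochs) with per-epoch reshuffling driven by an explicit seed, so a
given (data, seed) pair always yields bit-identical training. The
network is implemented directly on NumPy arrays (float32, im2col +
GEMM); its forward pass is verified against a brute-force direct
convolution in the test suite. An optional second 2x2 convolution
stage can be enabled in the config; it is off by default.

The baseline is a one-vs-one RBF-kernel SVM (scikit-learn) on z-scored
TDAR features, with pairwise-coupling probability calibration so both
model kinds expose the same (labels, probabilities) predict contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .config import RunConfig

__all__ = [
    "CnnSpec",
    "TrainedModel",
    "build_cnn",
    "train_cnn",
    "train_svm",
    "predict",
]


@dataclass(frozen=True)
class CnnSpec:
    """Architecture description with consistent chained layer shapes."""

    in_channels: int
    n_classes: int
    grid_side: int
    kernel: int
    filters: int
    fc_size: int
    dropout: float
    two_stage: bool
    conv_out: int  # spatial side after the first convolution
    flatten: int  # units entering the fully connected layer
    param_count: int


@dataclass
class TrainedModel:
    """A fitted classifier of either kind with a shared predict contract."""

    kind: str  # "cnn" or "svm"
    classes_: np.ndarray  # label ordering fixed at fit time
    seed: int
    # cnn
    spec: CnnSpec | None = None
    weights: dict = field(default_factory=dict)
    loss_history: list = field(default_factory=list)
    # svm
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    svc: SVC | None = None


def build_cnn(n_channels: int, n_classes: int, cfg: RunConfig | None = None) -> CnnSpec:
    """Chain the layer shapes and compute the exact parameter count."""
    cfg = cfg or RunConfig()
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_channels < 1:
        raise ValueError("need at least 1 input channel")
    conv_out = cfg.grid_side - cfg.conv_kernel + 1
    if conv_out < 1:
        raise ValueError(
            f"kernel {cfg.conv_kernel} does not fit a {cfg.grid_side}x{cfg.grid_side} grid"
        )
    k, m = cfg.conv_kernel, cfg.conv_filters
    params = k * k * n_channels * m + m
    if cfg.cnn_two_stage:
        if conv_out < 2:
            raise ValueError("second 2x2 conv stage does not fit the feature map")
        params += 2 * 2 * m * m + m
        flatten = (conv_out - 1) ** 2 * m
    else:
        flatten = conv_out * conv_out * m
    params += flatten * cfg.fc_size + cfg.fc_size
    params += cfg.fc_size * n_classes + n_classes
    return CnnSpec(
        in_channels=n_channels,
        n_classes=n_classes,
        grid_side=cfg.grid_side,
        kernel=cfg.conv_kernel,
        filters=m,
        fc_size=cfg.fc_size,
        dropout=cfg.dropout,
        two_stage=cfg.cnn_two_stage,
        conv_out=conv_out,
        flatten=flatten,
        param_count=params,
    )


def _im2col(maps: np.ndarray, k: int) -> np.ndarray:
    """[n x S x S x C] feature maps -> [n x P x k*k*C] patch matrix.

    Positions are row-major over the valid output grid; each patch is
    flattened in (row, col, channel) C-order.
    """
    n, s, _, c = maps.shape
    out = s - k + 1
    cols = np.empty((n, out * out, k * k * c), dtype=maps.dtype)
    p = 0
    for i in range(out):
        for j in range(out):
            cols[:, p, :] = maps[:, i : i + k, j : j + k, :].reshape(n, -1)
            p += 1
    return cols


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights: dict, spec: CnnSpec, cols: np.ndarray, dropout_mask=None):
    """Forward pass on precomputed conv patches; returns cache for backprop."""
    n, p, f = cols.shape
    # one large GEMM instead of n small batched ones
    z1 = (cols.reshape(n * p, f) @ weights["W1"]).reshape(n, p, -1) + weights["b1"]
    a1 = np.maximum(z1, 0.0)
    if spec.two_stage:
        n = a1.shape[0]
        fmap = a1.reshape(n, spec.conv_out, spec.conv_out, spec.filters)
        cols2 = _im2col(fmap, 2)
        z1b = cols2 @ weights["W1b"] + weights["b1b"]
        a1b = np.maximum(z1b, 0.0)
        flat = a1b.reshape(n, -1)
        stage2 = (cols2, z1b)
    else:
        flat = a1.reshape(a1.shape[0], -1)
        stage2 = None
    z2 = flat @ weights["W2"] + weights["b2"]
    a2 = np.maximum(z2, 0.0)
    a2d = a2 * dropout_mask if dropout_mask is not None else a2
    logits = a2d @ weights["W3"] + weights["b3"]
    probs = _softmax(logits)
    return probs, (cols, z1, stage2, flat, z2, a2d)


def forward_probs(model: TrainedModel, grids: np.ndarray) -> np.ndarray:
    """Inference-mode class probabilities for [n x S x S x C] grids."""
    spec = model.spec
    grids = np.ascontiguousarray(grids, dtype=np.float32)
    if grids.ndim != 4 or grids.shape[1:] != (spec.grid_side, spec.grid_side, spec.in_channels):
        raise ValueError(
            f"expected grids of shape [n x {spec.grid_side} x {spec.grid_side} "
            f"x {spec.in_channels}], got {grids.shape}"
        )
    cols = _im2col(grids, spec.kernel)
    probs, _ = _forward(model.weights, spec, cols)
    return probs.astype(float)


def train_cnn(
    spec: CnnSpec,
    grids: np.ndarray,
    labels: np.ndarray,
    seed: int,
    cfg: RunConfig | None = None,
) -> TrainedModel:
    """Mini-batch SGD with momentum; bit-reproducible for a given seed."""
    cfg = cfg or RunConfig()
    grids = np.ascontiguousarray(grids, dtype=np.float32)
    labels = np.asarray(labels)
    if grids.ndim != 4 or grids.shape[0] != labels.shape[0]:
        raise ValueError("grids and labels disagree")
    classes = np.unique(labels)
    if classes.shape[0] != spec.n_classes:
        raise ValueError(
            f"spec expects {spec.n_classes} classes, training data holds {classes.shape[0]}"
        )
    y = np.searchsorted(classes, labels).astype(np.int64)
    n = grids.shape[0]

    rng = np.random.default_rng(seed)
    k, m, c = spec.kernel, spec.filters, spec.in_channels

    def he(fan_in: int, shape) -> np.ndarray:
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    weights = {
        "W1": he(k * k * c, (k * k * c, m)),
        "b1": np.zeros(m, dtype=np.float32),
        "W2": he(spec.flatten, (spec.flatten, spec.fc_size)),
        "b2": np.zeros(spec.fc_size, dtype=np.float32),
        "W3": he(spec.fc_size, (spec.fc_size, spec.n_classes)),
        "b3": np.zeros(spec.n_classes, dtype=np.float32),
    }
    if spec.two_stage:
        weights["W1b"] = he(4 * m, (4 * m, m))
        weights["b1b"] = np.zeros(m, dtype=np.float32)

    velocity = {name: np.zeros_like(w) for name, w in weights.items()}
    cols_all = _im2col(grids, k)
    keep = 1.0 - spec.dropout
    lr, mu, bs = cfg.learning_rate, cfg.momentum, cfg.batch_size
    eye = np.eye(spec.n_classes, dtype=np.float32)

    history: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            cols = cols_all[idx]
            yb = y[idx]
            b = idx.shape[0]
            if spec.dropout > 0:
                mask = (rng.random(
                    (b, spec.fc_size)) < keep).astype(np.float32) / keep
            else:
                mask = None
            probs, cache = _forward(weights, spec, cols, dropout_mask=mask)
            _cols, z1, stage2, flat, z2, a2d = cache
            eps = np.finfo(np.float32).tiny
            epoch_loss += float(-np.log(probs[np.arange(b), yb] + eps).sum())

            grads = {}
            dz3 = (probs - eye[yb]) / b
            grads["W3"] = a2d.T @ dz3
            grads["b3"] = dz3.sum(axis=0)
            da2 = dz3 @ weights["W3"].T
            if mask is not None:
                da2 = da2 * mask
            dz2 = da2 * (z2 > 0)
            grads["W2"] = flat.T @ dz2
            grads["b2"] = dz2.sum(axis=0)
            dflat = dz2 @ weights["W2"].T
            if spec.two_stage:
                cols2, z1b = stage2
                dz1b = dflat.reshape(z1b.shape) * (z1b > 0)
                grads["W1b"] = cols2.reshape(-1, 4 * m).T @ dz1b.reshape(-1, m)
                grads["b1b"] = dz1b.sum(axis=(0, 1))
                dcols2 = dz1b @ weights["W1b"].T
                da1 = _col2im_grad(dcols2, spec.conv_out, 2, m).reshape(
                    b, spec.conv_out * spec.conv_out, m
                )
            else:
                da1 = dflat.reshape(z1.shape)
            dz1 = da1 * (z1 > 0)
            grads["W1"] = _cols.reshape(-1, k * k * c).T @ dz1.reshape(-1, m)
            grads["b1"] = dz1.sum(axis=(0, 1))

            for name in weights:
                velocity[name] = (mu * velocity[name] - lr * grads[name]).astype(
                    np.float32
                )
                weights[name] += velocity[name]
        history.append(epoch_loss / n)

    return TrainedModel(
        kind="cnn",
        classes_=classes,
        seed=seed,
        spec=spec,
        weights=weights,
        loss_history=history,
    )


def _col2im_grad(dcols: np.ndarray, s: int, k: int, c: int) -> np.ndarray:
    """Scatter patch gradients [n x P x k*k*c] back onto [n x s x s x c] maps."""
    n = dcols.shape[0]
    out = s - k + 1
    maps = np.zeros((n, s, s, c), dtype=dcols.dtype)
    p = 0
    for i in range(out):
        for j in range(out):
            maps[:, i : i + k, j : j + k, :] += dcols[:, p, :].reshape(n, k, k, c)
            p += 1
    return maps


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: RunConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """One-vs-one SVM on z-scored features with probability calibration."""
    cfg = cfg or RunConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree")
    classes = np.unique(labels)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes to train an SVM")
    mean = features.mean(axis=0)
    std = features.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    z = (features - mean) / std
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True in favour of an external
        # calibration wrapper; the built-in pairwise coupling is what we want
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(
            kernel=cfg.svm_kernel,
            C=cfg.svm_c,
            gamma="scale",
            probability=True,
            random_state=int(seed),
        )
        svc.fit(z, labels)
    return TrainedModel(
        kind="svm",
        classes_=svc.classes_,
        seed=seed,
        scaler_mean=mean,
        scaler_std=std,
        svc=svc,
    )


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, class probabilities); rows of the probabilities sum to 1.

    The label is the argmax of the probability row; on ties NumPy's
    argmax picks the lowest class index.
    """
    if model.kind == "cnn":
        probs = forward_probs(model, np.asarray(features))
    elif model.kind == "svm":
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != model.scaler_mean.shape[0]:
            raise ValueError("feature dimension does not match the fitted SVM")
        z = (features - model.scaler_mean) / model.scaler_std
        probs = model.svc.predict_proba(z)
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    labels = model.classes_[np.argmax(probs, axis=1)]
    return labels, probs
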