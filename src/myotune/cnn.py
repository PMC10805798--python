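"""Section-depth-parameterised CNN for sEMG-image classification.

The network has three sections, each holding ``section_depth`` identical
convolutional blocks (2D convolution -> batch normalisation -> ReLU), with a
1x2 max-pool along the time axis after each of the first two sections, then
a fully connected softmax layer.  The total number of convolutional layers
is therefore ``3 * section_depth``.  Filter counts per section scale as
``round(base_filters * 2**(k-1) / sqrt(section_depth))`` so that the total
parameter count stays nearly constant across depths.

Training is plain stochastic gradient descent with momentum (SGDM) and an
L2 weight penalty on convolution and dense kernels, with optional on-the-fly
augmentation of training batches.  Everything is implemented directly on
numpy arrays (float32): convolutions run as im2col matrix products, and
batch normalisation always uses the statistics of the batch being processed
— evaluation is done in a single pass over the full set, which keeps
prediction a pure, deterministic function of the weights and the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ConfigError, DataError, DivergenceError
from .preprocess import AugmentationSpec, SEMGImageSet, augment_images

_EPS = 1e-5


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class CNNSpec:
    """Architecture description; ``section_depth`` is the tuned dimension."""

    section_depth: int = 2
    n_sections: int = 3
    base_filters: int = 16
    input_shape: tuple[int, int] = (8, 40)  # channels x samples
    n_classes: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.section_depth <= 3:
            raise ConfigError("section_depth must be in [1, 3]")
        if self.n_sections != 3:
            raise ConfigError("the architecture is defined with 3 sections")
        if self.base_filters < 1 or self.n_classes < 2:
            raise ConfigError("base_filters >= 1 and n_classes >= 2 required")
        h, w = self.input_shape
        if h < 1 or w < 4:
            raise ConfigError(
                f"input {self.input_shape} too small for two 1x2 pooling stages"
            )

    def section_filters(self) -> list[int]:
        """Filters per block in section k: round(base*2^(k-1)/sqrt(depth))."""
        return [
            max(1, round(self.base_filters * 2 ** (k - 1) / math.sqrt(self.section_depth)))
            for k in range(1, self.n_sections + 1)
        ]

    @property
    def n_conv_layers(self) -> int:
        return self.n_sections * self.section_depth


@dataclass(frozen=True)
class TrainConfig:
    """SGDM training settings."""

    learning_rate: float = 3e-3
    momentum: float = 0.9
    l2_strength: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 50
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigError("momentum must be in [0, 1)")
        if self.l2_strength < 0:
            raise ConfigError("l2_strength must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("batch_size and max_epochs must be >= 1")


@dataclass
class CERReport:
    """Classification error rate with its binomial confidence interval."""

    cer: float
    n: int
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------
# layers (parameters live in plain dicts of float32 arrays)


class _Conv:
    """3x3 same-padding convolution as an im2col matrix product."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, std, size=(c_in * 9, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out
        self._col: Optional[np.ndarray] = None
        self._shape: Optional[tuple] = None

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
        return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * 9
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        col = self._im2col(x)
        if train:
            self._col, self._shape = col, (n, c, h, w)
        out = col @ self.w + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray, l2: float) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.c_out
        )
        self.dw = self._col.T @ dflat + np.float32(l2) * self.w
        self.db = dflat.sum(axis=0)
        # dx: full correlation of dout with the rotated kernels
        w4 = self.w.reshape(self.c_in, 3, 3, self.c_out)
        m = np.ascontiguousarray(
            w4[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)
        ).reshape(self.c_out * 9, self.c_in)
        dcol = self._im2col(dout)
        dx = (dcol @ m).reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        self._col = None
        return np.ascontiguousarray(dx)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def n_params(self) -> int:
        return self.w.size + self.b.size

    def describe(self) -> str:
        return f"conv3x3({self.c_in}->{self.c_out})"


class _BatchNorm:
    """Per-feature-map normalisation using the current batch statistics."""

    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.c = c

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mean = x.mean(axis=(0, 2, 3), keepdims=True)
        var = x.var(axis=(0, 2, 3), keepdims=True)
        invstd = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mean) * invstd
        if train:
            self._xhat, self._invstd = xhat, invstd
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray, l2: float) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        dx = (
            invstd
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )
        self._xhat = self._invstd = None
        return dx.astype(np.float32)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def n_params(self) -> int:
        return 2 * self.c

    def describe(self) -> str:
        return f"batchnorm({self.c})"


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray, l2: float) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return {}

    def grads(self):
        return {}

    def n_params(self) -> int:
        return 0

    def describe(self) -> str:
        return "relu"


class _MaxPoolTime:
    """1x2 max-pool along the time axis (channel axis is only 8 rows)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        w2 = w // 2
        xr = x[:, :, :, : 2 * w2].reshape(n, c, h, w2, 2)
        idx = xr.argmax(axis=4)
        out = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return out

    def backward(self, dout: np.ndarray, l2: float) -> np.ndarray:
        n, c, h, w = self._shape
        w2 = w // 2
        dxr = np.zeros((n, c, h, w2, 2), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=4)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, :, : 2 * w2] = dxr.reshape(n, c, h, 2 * w2)
        self._idx = None
        return dx

    def params(self):
        return {}

    def grads(self):
        return {}

    def n_params(self) -> int:
        return 0

    def describe(self) -> str:
        return "maxpool1x2(time)"


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / d_in)
        self.w = rng.normal(0.0, std, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.d_in, self.d_out = d_in, d_out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n = x.shape[0]
        flat = x.reshape(n, -1)
        if train:
            self._flat, self._shape = flat, x.shape
        return flat @ self.w + self.b

    def backward(self, dout: np.ndarray, l2: float) -> np.ndarray:
        self.dw = self._flat.T @ dout + np.float32(l2) * self.w
        self.db = dout.sum(axis=0)
        dx = (dout @ self.w.T).reshape(self._shape)
        self._flat = None
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def n_params(self) -> int:
        return self.w.size + self.b.size

    def describe(self) -> str:
        return f"dense({self.d_in}->{self.d_out})+softmax"


# ---------------------------------------------------------------------------
# model


class CNN:
    """Instantiated network; see :func:`build_cnn`."""

    def __init__(self, spec: CNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        h, w = spec.input_shape
        filters = spec.section_filters()
        layers: list = []
        c_in = 1
        for k in range(spec.n_sections):
            for _ in range(spec.section_depth):
                layers.append(_Conv(c_in, filters[k], rng))
                layers.append(_BatchNorm(filters[k]))
                layers.append(_ReLU())
                c_in = filters[k]
            if k < 2:
                layers.append(_MaxPoolTime())
                w = w // 2
                if w < 1:
                    raise ConfigError("input too small for two pooling stages")
        layers.append(_Dense(c_in * h * w, spec.n_classes, rng))
        self.layers = layers

    # -- bookkeeping ------------------------------------------------------
    @property
    def parameter_count(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def describe(self) -> list[str]:
        return [layer.describe() for layer in self.layers]

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params().items()} for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, wd in zip(self.layers, weights):
            for k, v in wd.items():
                layer.params()[k][...] = v

    # -- compute ----------------------------------------------------------
    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)[:, None, :, :]
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def loss_and_backward(
        self, images: np.ndarray, labels: np.ndarray, l2: float
    ) -> tuple[float, int]:
        """One forward/backward pass; returns (loss, correct count)."""
        z = self.logits(images, train=True)
        n_correct = int(np.count_nonzero(z.argmax(axis=1) == labels))
        z = z - z.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        n = len(labels)
        loss = -float(logp[np.arange(n), labels].mean())
        p = np.exp(logp)
        dz = p
        dz[np.arange(n), labels] -= 1.0
        dz /= np.float32(n)
        grad = dz.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad, l2)
        return loss, n_correct

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predicted class ids; one full-batch pass (batch-statistics BN)."""
        return self.logits(images, train=False).argmax(axis=1)


@dataclass
class TrainedModel:
    """A trained network plus its training history."""

    spec: CNNSpec
    model: CNN
    history: list = field(default_factory=list)  # per-epoch dicts
    config: Optional[TrainConfig] = None

    def predict(self, imgs: SEMGImageSet) -> np.ndarray:
        return self.model.predict(imgs.images)

    def evaluate(self, imgs: SEMGImageSet) -> float:
        return classification_error_rate(self.predict(imgs), imgs.labels)

    def report(self, imgs: SEMGImageSet, level: float = 0.95) -> CERReport:
        cer = self.evaluate(imgs)
        n = len(imgs)
        return CERReport(cer, n, cer_confidence_interval(cer, n, level))


# ---------------------------------------------------------------------------
# operations


def build_cnn(spec: CNNSpec, seed: int = 0) -> CNN:
    """Instantiate the three-section architecture with seeded He init."""
    return CNN(spec, seed=seed)


def train_cnn(
    model: CNN,
    train: SEMGImageSet,
    val: SEMGImageSet,
    cfg: TrainConfig,
    aug: Optional[AugmentationSpec] = None,
) -> TrainedModel:
    """SGDM training with L2 penalty and optional on-the-fly augmentation.

    Augmentation touches training batches only; validation images are used
    as-is.  The returned model carries the weights of the best
    validation-CER epoch.  Deterministic given ``cfg.seed``.
    """
    if len(train) == 0:
        raise DataError("empty training set")
    if train.labels.max() >= model.spec.n_classes or train.labels.min() < 0:
        raise DataError("training labels incompatible with n_classes")
    rng = np.random.default_rng(cfg.seed)

    # single float32 copy up front keeps every pass allocation-light
    train = SEMGImageSet(train.images.astype(np.float32), train.labels)
    if len(val):
        val = SEMGImageSet(val.images.astype(np.float32), val.labels)

    net = build_cnn(model.spec, seed=0)
    net.set_weights(model.get_weights())

    velocity = [
        {k: np.zeros_like(v) for k, v in layer.params().items()}
        for layer in net.layers
    ]
    n = len(train)
    best_val = math.inf
    best_weights = net.get_weights()
    history: list[dict] = []
    stall = 0
    for epoch in range(cfg.max_epochs):
        epoch_imgs = train
        if aug is not None:
            epoch_imgs = augment_images(
                train, replace(aug, seed=int(rng.integers(0, 2**31 - 1)))
            )
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, n_ok = net.loss_and_backward(
                epoch_imgs.images[idx], epoch_imgs.labels[idx], cfg.l2_strength
            )
            if not math.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} with config {cfg}"
                )
            losses.append(loss)
            correct += n_ok
            if cfg.learning_rate > 0:
                for layer, vel in zip(net.layers, velocity):
                    grads = layer.grads()
                    for k, p in layer.params().items():
                        v = vel[k]
                        v *= np.float32(cfg.momentum)
                        v -= np.float32(cfg.learning_rate) * grads[k]
                        p += v
        # training CER as observed on the (possibly augmented) batches
        train_cer = 1.0 - correct / n
        val_cer = (
            classification_error_rate(net.predict(val.images), val.labels)
            if len(val)
            else math.nan
        )
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "train_cer": train_cer,
                "val_cer": val_cer,
            }
        )
        if len(val) and val_cer < best_val - 1e-12:
            best_val = val_cer
            best_weights = net.get_weights()
            stall = 0
        else:
            stall += 1
            if len(val) and stall > cfg.early_stop_patience:
                break
    if len(val):
        net.set_weights(best_weights)
    return TrainedModel(model.spec, net, history, cfg)


def classification_error_rate(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of mismatched predictions, in [0, 1]."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or len(labels) < 1:
        raise DataError(
            f"predictions {predictions.shape} and labels {labels.shape} mismatch"
        )
    return float(np.mean(predictions != labels))


def cer_confidence_interval(
    cer: float, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Binomial confidence interval for an error rate (Wilson score default).

    ``method='wald'`` selects the symmetric normal-approximation interval,
    clipped to [0, 1].
    """
    if not 0.0 <= cer <= 1.0:
        raise DataError("cer must be in [0, 1]")
    if n < 1:
        raise DataError("n must be >= 1")
    if not 0.0 < level < 1.0:
        raise DataError("level must be in (0, 1)")
    if method not in ("wilson", "wald"):
        raise ConfigError(f"unknown CI method {method!r}")
    count = cer * n
    sm_method = "wilson" if method == "wilson" else "normal"
    low, high = proportion_confint(count, n, alpha=1.0 - level, method=sm_method)
    low = 0.0 if count <= 0 else float(np.clip(low, 0.0, 1.0))
    high = 1.0 if count >= n else float(np.clip(high, 0.0, 1.0))
    return low, high
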