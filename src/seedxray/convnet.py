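"""A minimal convolutional network for binary seed classification.

Architecture: repeated blocks of (3x3 stride-1 same-padding convolution ->
ReLU -> 2x2 max-pool), a fully-connected layer and a softmax over the two
classes, trained with Adam on a cross-entropy loss.  Implemented directly
on numpy (im2col convolutions, explicit backward passes) so it trains on a
single CPU at desk scale; depth, channel widths and the input resolution
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ParameterError

KERNEL = 3  # 3x3 filters, stride 1, same padding, in every conv stage
PAD = 1


@dataclass(frozen=True)
class ConvNetConfig:
    input_size: int = 224
    channels: tuple[int, ...] = (16, 32, 64)
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    rng_seed: int = 0

    def validate(self) -> None:
        if self.input_size % (2 ** len(self.channels)) != 0:
            raise ParameterError(
                "input_size must be divisible by 2^n_blocks for the pooling cascade"
            )
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ParameterError("invalid training hyperparameters")


def feature_map_sizes(config: ConvNetConfig) -> list[int]:
    """Spatial size after each block: same-conv keeps size, pooling halves it."""
    sizes = [config.input_size]
    for _ in config.channels:
        sizes.append(sizes[-1] // 2)
    return sizes


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for 3x3 same convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (KERNEL, KERNEL), axis=(2, 3))
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * KERNEL * KERNEL)


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * KERNEL * KERNEL
        self.w = (rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, KERNEL, KERNEL))).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        n, _, h, w = x.shape
        out = self._cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, co, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, co)
        self.dw = (dflat.T @ self._cols).reshape(self.w.shape)
        self.db = dflat.sum(axis=0)
        # gradient w.r.t. input = same-conv of dout with rotated, transposed kernels
        w_rot = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols = _im2col(dout)
        dx = cols @ w_rot.reshape(w_rot.shape[0], -1).T
        return dx.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def params(self):
        return [("w", self), ("b", self)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        blocks = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNetModel:
    """Trained network: conv blocks + dense head, with the label vocabulary."""

    def __init__(self, config: ConvNetConfig, classes: np.ndarray):
        config.validate()
        self.config = config
        self.classes = classes
        rng = np.random.default_rng(config.rng_seed)
        self.convs: list[_Conv] = []
        self.relus: list[_ReLU] = []
        self.pools: list[_MaxPool2] = []
        c_in = 1
        for c_out in config.channels:
            self.convs.append(_Conv(c_in, c_out, rng))
            self.relus.append(_ReLU())
            self.pools.append(_MaxPool2())
            c_in = c_out
        final = feature_map_sizes(config)[-1]
        self.dense = _Dense(c_in * final * final, len(classes), rng)

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x[:, None, :, :].astype(np.float32)
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        self._flat_shape = h.shape
        return self.dense.forward(h.reshape(h.shape[0], -1))

    def _backward(self, dlogits: np.ndarray) -> None:
        dh = self.dense.backward(dlogits).reshape(self._flat_shape)
        for conv, relu, pool in zip(
            reversed(self.convs), reversed(self.relus), reversed(self.pools)
        ):
            dh = conv.backward(relu.backward(pool.backward(dh)))

    def _parameters(self):
        layers = self.convs + [self.dense]
        for layer in layers:
            yield layer, "w"
            yield layer, "b"

    # -- public API ---------------------------------------------------------
    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        out = []
        for start in range(0, len(images), batch_size):
            out.append(_softmax(self._forward(images[start : start + batch_size])))
        return np.concatenate(out)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.classes[self.predict_proba(images).argmax(axis=1)]


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError(f"binary classifier needs 2 classes, got {classes.size}")
    return classes, np.searchsorted(classes, y)


def train_convnet(
    train_images: np.ndarray,
    train_labels,
    val_images: np.ndarray | None = None,
    val_labels=None,
    config: ConvNetConfig | None = None,
) -> tuple[ConvNetModel, pd.DataFrame]:
    """Train with Adam; deterministic given config.rng_seed.

    Returns the model and a per-epoch history (train loss/accuracy and,
    when a validation set is given, validation accuracy).
    """
    if config is None:
        config = ConvNetConfig()
    x = np.asarray(train_images, dtype=np.float32)
    if x.ndim != 3 or x.shape[1:] != (config.input_size, config.input_size):
        raise ParameterError(
            f"train images must be (n, {config.input_size}, {config.input_size}) grayscale"
        )
    if len(x) == 0:
        raise ParameterError("empty training set")
    classes, y = _encode_labels(train_labels)
    model = ConvNetModel(config, classes)

    # Adam state
    mom = [
        (np.zeros_like(getattr(layer, attr)), np.zeros_like(getattr(layer, attr)))
        for layer, attr in model._parameters()
    ]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rng = np.random.default_rng(config.rng_seed + 1)
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model._forward(x[idx])
            probs = _softmax(logits)
            losses.append(float(-np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12).mean()))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), y[idx]] -= 1.0
            model._backward((dlogits / len(idx)).astype(np.float32))
            step += 1
            for (layer, attr), state in zip(model._parameters(), mom):
                grad = getattr(layer, "d" + attr)
                m, v = state
                m *= beta1
                m += (1 - beta1) * grad
                v *= beta2
                v += (1 - beta2) * grad**2
                mhat = m / (1 - beta1**step)
                vhat = v / (1 - beta2**step)
                getattr(layer, attr)[...] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        row = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": 100.0 * correct / len(x),
        }
        if val_images is not None and val_labels is not None and len(val_images):
            row["val_accuracy"] = evaluate_convnet(model, val_images, val_labels)[0]
        rows.append(row)
    return model, pd.DataFrame(rows)


def evaluate_convnet(model: ConvNetModel, images: np.ndarray, labels) -> tuple[float, pd.DataFrame]:
    """Accuracy (percent) and a per-image prediction table."""
    images = np.asarray(images, dtype=np.float32)
    if len(images) == 0:
        raise ParameterError("empty evaluation set")
    y = np.asarray(labels)
    proba = model.predict_proba(images)
    pred = model.classes[proba.argmax(axis=1)]
    table = pd.DataFrame({"true": y, "predicted": pred})
    for cls, col in zip(model.classes, proba.T):
        table[f"p_{cls}"] = col
    return 100.0 * float(np.mean(pred == y)), table


def to_pseudocolor(image: np.ndarray) -> np.ndarray:
    """Replicate a grayscale image to 3 channels (for color-input networks)."""
    return np.repeat(np.asarray(image)[..., None], 3, axis=-1)
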