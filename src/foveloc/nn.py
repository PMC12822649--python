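"""Minimal CPU neural-network engine (conv / pool / dense, Adam, BCE).

The classifier recipe in this package needs exactly one architecture
family: stacks of 3x3 same-padded convolutions with ReLU, 2x2 max
pooling, dense layers, and a sigmoid binary output trained with
binary cross-entropy and Adam.  This module implements those pieces
directly on numpy, with convolutions lowered to BLAS matrix products via
im2col, which is fast enough to train the full recipe on a CPU in
minutes at the image sizes used here.

All parameters are float32; initialization is He-normal from a caller
supplied generator, so a fixed seed gives bit-reproducible training.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError


class Layer:
    """Base layer: forward caches what backward needs; params exposed."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 stride-1 convolution with 'same' zero padding, NHWC layout."""

    kind = "conv"

    def __init__(self, in_channels: int, filters: int,
                 rng: np.random.Generator) -> None:
        self.in_channels = in_channels
        self.filters = filters
        fan_in = 9 * in_channels
        self.w = (rng.standard_normal((fan_in, filters))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def width(self) -> int:
        return self.filters

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def _patches(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        sw = sliding_window_view(xp, (3, 3), axis=(1, 2))  # N,H,W,C,3,3
        n, h, w = x.shape[:3]
        return np.ascontiguousarray(sw.transpose(0, 1, 2, 4, 5, 3)
                                    ).reshape(n * h * w, 9 * self.in_channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._patches(x)
        n, h, w, _ = x.shape
        return (self._cols @ self.w + self.b).reshape(n, h, w, self.filters)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dy_flat = dy.reshape(n * h * w, self.filters)
        self.dw[...] = self._cols.T @ dy_flat
        self.db[...] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.w.T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, 1:-1, 1:-1, :]


class MaxPool2(Layer):
    """2x2 stride-2 max pooling (spatial dims must be even)."""

    kind = "pool"
    width = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ConfigurationError("max pooling requires even spatial dims")
        self._xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        self._out = self._xr.max(axis=(2, 4))
        return self._out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._xr == self._out[:, :, None, :, None, :]
        dxr = mask * dy[:, :, None, :, None, :]
        n, hh, _, ww, _, c = self._xr.shape
        return dxr.reshape(n, hh * 2, ww * 2, c)


class Flatten(Layer):
    kind = "flatten"
    width = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    kind = "dense"

    def __init__(self, in_features: int, units: int,
                 rng: np.random.Generator) -> None:
        self.units = units
        self.w = (rng.standard_normal((in_features, units))
                  * np.sqrt(2.0 / in_features)).astype(np.float32)
        self.b = np.zeros(units, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def width(self) -> int:
        return self.units

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


class ReLU(Layer):
    kind = "relu"
    width = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class Adam:
    """Adam optimizer with bias correction (lr 1e-3 default)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """A feed-forward stack ending in a single sigmoid unit."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        probs = [sigmoid(self.logits(x[i:i + batch_size]))
                 for i in range(0, len(x), batch_size)]
        return np.concatenate(probs) if probs else np.empty(0)

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   optimizer: Adam) -> tuple[float, np.ndarray]:
        z = self.logits(x)
        p = sigmoid(z)
        loss = bce_loss(p, y)
        dz = ((p - y) / len(y)).astype(np.float32)[:, None]
        dy = dz
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        optimizer.step(self.all_grads())
        return loss, p

    def all_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def all_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.all_params()))

    def architecture(self) -> list[tuple[str, int | None]]:
        """(kind, width) per layer, for audit against the fixed recipe."""
        return [(layer.kind, layer.width) for layer in self.layers]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.all_params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.all_params(), weights):
            p[...] = w

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.all_params())}
        np.savez(Path(path).with_suffix(".npz") if Path(path).suffix == ""
                 else Path(path), meta=json.dumps(meta or {}), **arrays)

    def load(self, path: str | Path) -> dict:
        data = np.load(path, allow_pickle=False)
        self.set_weights([data[f"p{i}"] for i in range(len(self.all_params()))])
        return json.loads(str(data["meta"]))
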