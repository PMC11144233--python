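"""A small convolutional network classifier, implemented on numpy.

Architecture (configurable): repeated blocks of 3x3 convolution + bias,
ReLU, 2x2 max-pooling, followed by dense layers and a softmax output
trained with cross-entropy.  Designed for desk-scale image grids
(e.g. 128 x 128 contour rasters) on a single CPU: convolutions run as
one matrix product per batch via im2col, everything is float32, and all
randomness (weight init, batch shuffling) flows from one seed so that
training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNNConfig", "CNNClassifier"]


@dataclass
class CNNConfig:
    conv_channels: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 3
    dense_widths: tuple[int, ...] = (64,)
    n_classes: int = 6
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        self.dense_widths = tuple(int(w) for w in self.dense_widths)
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for name in ("kernel_size", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (same-padding)")
        if any(c < 1 for c in self.conv_channels) or any(w < 1 for w in self.dense_widths):
            raise ValueError("channel and dense widths must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


# ---------------------------------------------------------------------------
# layers (NHWC, float32)

class _Conv:
    """Same-padded convolution; skips the input gradient when first layer."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 first: bool):
        fan_in = k * k * in_ch
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.in_ch = in_ch
        self.first = first
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
        n, h, w = x.shape[:3]
        # column order (k, k, C) must match W's fan-in layout
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * self.in_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._col = self._im2col(x)
        n, h, w, _ = x.shape
        out = self._col @ self.W + self.b
        return out.reshape(n, h, w, self.W.shape[1])

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        n, h, w, _ = self._shape
        g = grad.reshape(n * h * w, -1)
        self.grads[0][...] = self._col.T @ g
        self.grads[1][...] = g.sum(axis=0)
        if self.first:
            return None
        dcol = g @ self.W.T                       # (NHW, k*k*C)
        k, c = self.k, self.in_ch
        p = k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        dcol = dcol.reshape(n, h, w, k, k, c)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcol[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, np.float32(0.0))


class _MaxPool2:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], grad[..., None], axis=-1)
        dx = dxr.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(n, h2 * 2, w2 * 2, c)


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = np.float32(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _SGD:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = np.float32(lr)

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class CNNClassifier:
    """Seeded, single-CPU CNN with a scikit-learn-like fit/predict surface."""

    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        self.layers: list | None = None
        self.classes_: np.ndarray | None = None

    # -- construction ------------------------------------------------------
    def _build(self, input_shape: tuple[int, int, int], n_out: int) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        h, w, c = input_shape
        layers: list = []
        in_ch = c
        for bi, out_ch in enumerate(cfg.conv_channels):
            layers.append(_Conv(in_ch, out_ch, cfg.kernel_size, rng, first=(bi == 0)))
            layers.append(_ReLU())
            layers.append(_MaxPool2())
            in_ch = out_ch
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValueError("input too small for the configured pooling depth")
        layers.append(_Flatten())
        n_in = h * w * in_ch
        for width in cfg.dense_widths:
            layers.append(_Dense(n_in, width, rng))
            layers.append(_ReLU())
            n_in = width
        layers.append(_Dense(n_in, n_out, rng))
        self.layers = layers

    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                break

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        """Train on images ``X`` (N, H, W, C) with string/int labels ``y``."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training set contains a single class")
        if self.classes_.size > self.cfg.n_classes:
            raise ValueError("more classes in y than cfg.n_classes")
        targets = np.searchsorted(self.classes_, y)
        # center inputs on the per-channel training mean; raw rasters are
        # dominated by the background level, which destabilizes training
        self.input_mean_ = X.mean(axis=(0, 1, 2), dtype=np.float32)
        X = X - self.input_mean_
        self._build(X.shape[1:], self.classes_.size)
        params = [p for layer in self.layers for p in layer.params]
        grads = [g for layer in self.layers for g in layer.grads]
        opt = (_Adam(params, self.cfg.learning_rate)
               if self.cfg.optimizer == "adam"
               else _SGD(params, self.cfg.learning_rate))
        rng = np.random.default_rng([self.cfg.seed, 1])
        n = X.shape[0]
        bs = min(self.cfg.batch_size, n)
        for _ in range(self.cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                logits = self._forward(X[idx])
                probs = _softmax(logits)
                grad = probs
                grad[np.arange(idx.size), targets[idx]] -= 1.0
                grad /= np.float32(idx.size)
                self._backward(grad.astype(np.float32))
                opt.step(grads)
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        if self.layers is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        X = X - self.input_mean_
        chunks = [_softmax(self._forward(X[i:i + batch_size]))
                  for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(chunks, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
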