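"""Minimal NumPy neural-network layers used by the dropout classifier.

Implements exactly what the model needs — im2col 2-D convolution, batch
normalisation, ReLU, inverted dropout, dense layers, residual blocks, a
softmax/cross-entropy head and Adam — with hand-written backward passes.
Tensor layout is NHWC throughout.  Batch-norm running statistics are used in
every prediction mode, so dropout masks are the only stochastic element of a
Monte-Carlo forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "Dense",
    "ResidualBlock",
    "Adam",
    "softmax",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    n, h, w, c = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, ho, wo, k, k, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
    )
    cols = np.ascontiguousarray(view).reshape(n * ho * wo, k * k * c)
    return cols, (n, h, w, c, ho, wo)


def _col2im(
    dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    n, h, w, c, ho, wo = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dxp = np.zeros((n, hp, wp, c), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, k, k, c)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += d[
                :, :, :, i, j, :
            ]
    if pad:
        return dxp[:, pad : hp - pad, pad : wp - pad, :]
    return dxp


class Conv2d:
    def __init__(
        self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng: np.random.Generator
    ):
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = k * k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = {"W": self.W, "b": self.b}
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, shape = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.W + self.b
        n, _, _, _, ho, wo = shape
        if train:
            self._cache = (cols, shape)
        return out.reshape(n, ho, wo, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, shape = self._cache
        d = dout.reshape(-1, dout.shape[-1])
        self.grads["W"][...] = cols.T @ d
        self.grads["b"][...] = d.sum(axis=0)
        dcols = d @ self.W.T
        return _col2im(dcols, shape, self.k, self.stride, self.pad)


class BatchNorm2d:
    """Per-channel batch norm over (N, H, W); running stats in eval mode."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.params = {"gamma": self.gamma, "beta": self.beta}
        self.grads = {"gamma": np.zeros_like(self.gamma), "beta": np.zeros_like(self.beta)}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (0, 1, 2)
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.grads["gamma"][...] = (dout * xhat).sum(axis=axes)
        self.grads["beta"][...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        return (inv / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class ReLU:
    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Inverted dropout: each unit zeroed with probability ``rate``.

    Active while training and — deliberately — during Monte-Carlo prediction
    passes, where the mask generator is supplied by the caller so that MC
    sampling is reproducible.
    """

    def __init__(self, rate: float):
        if not 0.0 < rate < 1.0:
            raise ValueError("dropout rate must be in (0, 1)")
        self.rate = rate
        self.params: dict = {}
        self.grads: dict = {}
        self._mask: np.ndarray | None = None

    def forward(
        self,
        x: np.ndarray,
        train: bool,
        rng: np.random.Generator | None = None,
        stochastic: bool = False,
    ) -> np.ndarray:
        if not train and not stochastic:
            return x
        if rng is None:
            raise ValueError("stochastic dropout pass requires an rng")
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = {"W": self.W, "b": self.b}
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.W.T


class ResidualBlock:
    """conv-BN-ReLU-conv-BN plus a (projected) skip, then ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.proj: Conv2d | None = None
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride, 0, rng)
        self.relu_out = ReLU()

    def sublayers(self) -> list:
        layers = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]
        if self.proj is not None:
            layers.append(self.proj)
        return layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        s = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu_out.forward(h + s, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        # branch gradient
        db = self.bn2.backward(d)
        db = self.conv2.backward(db)
        db = self.relu1.backward(db)
        db = self.bn1.backward(db)
        db = self.conv1.backward(db)
        # skip gradient
        ds = self.proj.backward(d) if self.proj is not None else d
        return db + ds


class Adam:
    """Adam over a flat list of (layer, param-name) slots; lr is mutable."""

    def __init__(self, layers: list, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots: list[tuple[object, str]] = []
        for layer in layers:
            for name in layer.params:
                self.slots.append((layer, name))
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads[name]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * (g * g)
            mhat = self.m[i] / b1c
            vhat = self.v[i] / b2c
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
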