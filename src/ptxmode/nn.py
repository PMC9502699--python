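"""Minimal convolutional-network engine on numpy.

Implements exactly the layer vocabulary the classifier needs — stride-1
same-padded 3×3 convolution (im2col + BLAS matmul), 2×2 max pooling,
inverted dropout, dense layers, ReLU, and softmax cross-entropy with Adam —
with full backpropagation, seeded initialization and single-file weight
save/load. Data layout is NHWC float32 throughout.

The engine is deliberately small: stride is fixed at 1 for convolutions and
2×2 for pooling, which covers the 6-block halving architecture used here
while keeping every backward pass a single reshaped matrix product.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D", "ReLU", "MaxPool2", "Dropout", "Flatten", "Dense",
    "Network", "Adam", "softmax", "cross_entropy_with_grad",
]

_F32 = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Extract k×k same-padded patches: (N,H,W,C) -> (N*H*W, k*k*C)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="constant")
    # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win.transpose(0, 1, 2, 4, 5, 3)
    N, H, W = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(win).reshape(N * H * W, k * k * x.shape[3])


class Conv2D:
    """3×3 (or any odd k) stride-1 convolution with 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator) -> None:
        if k % 2 != 1:
            raise ValueError(f"kernel side {k} must be odd for same padding")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in = k * k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, c_out)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, H, W, _ = x.shape
        cols = _im2col(x, self.k)
        if training:
            self._cols, self._in_shape = cols, x.shape
        out = cols @ self.W + self.b
        return out.reshape(N, H, W, self.c_out)

    def backward(self, dout: np.ndarray,
                 need_dx: bool = True) -> np.ndarray | None:
        N, H, W, _ = self._in_shape
        dflat = dout.reshape(N * H * W, self.c_out)
        self.db[:] = dflat.sum(axis=0)
        self.dW[:] = self._cols.T @ dflat
        self._cols = None
        if not need_dx:
            return None
        # dx = dout (*) rot180(W) with channels swapped
        Wk = self.W.reshape(self.k, self.k, self.c_in, self.c_out)
        Wback = Wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(
            self.k * self.k * self.c_out, self.c_in)
        dcols = _im2col(dout, self.k)
        return (dcols @ Wback.astype(_F32)).reshape(N, H, W, self.c_in)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class MaxPool2:
    """2×2 max pooling, stride 2; gradient is split evenly across ties."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial size {H}x{W} not divisible by 2")
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C)
        out = xr.max(axis=(2, 4))
        if training:
            self._cache = (xr, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, out = self._cache
        self._cache = None
        mask = (xr == out[:, :, None, :, None, :])
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * (dout[:, :, None, :, None, :] / counts)
        N, Hh, _, Wh, _, C = xr.shape
        return dxr.reshape(N, Hh * 2, Wh * 2, C).astype(_F32)

    def params(self):
        return []


class Dropout:
    """Inverted dropout: active only in training mode, identity otherwise."""

    def __init__(self, rate: float) -> None:
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(_F32) \
            / _F32(1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask if self._mask is not None else dout
        self._mask = None
        return dx

    def params(self):
        return []


class Flatten:
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he") -> None:
        if init == "he":
            sd = np.sqrt(2.0 / n_in)
        elif init == "glorot":
            sd = np.sqrt(2.0 / (n_in + n_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.W = rng.normal(0.0, sd, size=(n_in, n_out)).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Network:
    """An ordered layer stack with forward/backward and weight snapshots."""

    def __init__(self, layers: list) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=_F32)
        for layer in self.layers:
            if isinstance(layer, Dropout):
                out = layer.forward(out, training, rng)
            else:
                out = layer.forward(out, training)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        grad = dout.astype(_F32)
        for i in reversed(range(len(self.layers))):
            layer = self.layers[i]
            # the input image needs no gradient: skip dx in the first layer
            if i == 0 and isinstance(layer, Conv2D):
                return layer.backward(grad, need_dx=False)
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError(
                f"weight count mismatch: {len(weights)} vs {len(params)}"
            )
        for (p, _), w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    def save(self, path) -> None:
        np.savez(path, *self.get_weights())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray,
                            y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(_F32)


class Adam:
    """Adam optimizer bound to a network's parameter list."""

    def __init__(self, network: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for p, _ in network.params()]
        self._v = [np.zeros_like(p) for p, _ in network.params()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.network.params(), self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= (self.lr * (m / bias1)
                  / (np.sqrt(v / bias2) + self.eps)).astype(p.dtype)
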