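"""Minimal CPU neural-network core: layers, backprop, Adam.

Layout is NCHW throughout. Layers are stateless with respect to activations:
``forward`` returns ``(y, cache)`` and ``backward(dy, cache)`` returns
``(dx, grads)`` where ``grads`` mirrors the layer's ``params`` dict. This keeps
the twin-branch (shared-weight) training loop explicit: both branches call the
same layer objects and their parameter gradients are summed by the caller.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Dense",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Flatten",
    "BatchNorm2d",
    "Sequential",
    "Adam",
    "he_uniform",
]

DTYPE = np.float32


def he_uniform(shape: tuple, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """He (Kaiming) uniform initialisation for ReLU stacks."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base layer. Subclasses override forward/backward; params returns the
    trainable arrays by name (possibly empty)."""

    def params(self) -> dict:
        return {}

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy, cache):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = he_uniform((out_features, in_features), in_features, rng)
        self.b = np.zeros(out_features, dtype=DTYPE)

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, train=False, rng=None):
        return x @ self.W.T + self.b, x

    def backward(self, dy, cache):
        x = cache
        dW = dy.T @ x
        db = dy.sum(axis=0)
        dx = dy @ self.W
        return dx, {"W": dW, "b": db}


def _pad_same(k: int) -> tuple[int, int]:
    # 'same' padding for stride-1 convolution; asymmetric when k is even
    total = k - 1
    return total // 2, total - total // 2


def im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Stride-1 same-padding patch matrix: (N*H*W, C*kh*kw)."""
    n, c, h, w = x.shape
    pt, pb = _pad_same(kh)
    pl, pr = _pad_same(kw)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * kh * kw
    )


def _col2im(dcols: np.ndarray, xshape: tuple, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = xshape
    pt, pb = _pad_same(kh)
    pl, pr = _pad_same(kw)
    dxp = np.zeros((n, c, h + pt + pb, w + pl + pr), dtype=dcols.dtype)
    d6 = dcols.reshape(n, h, w, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + w] += d6[:, :, i, j]
    return dxp[:, :, pt : pt + h, pl : pl + w]


class Conv2d(Layer):
    """Stride-1, 'same'-padded 2-D convolution (spatial size preserved)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_side: int,
                 rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_side
        fan_in = in_channels * kernel_side * kernel_side
        self.W = he_uniform((out_channels, in_channels, kernel_side, kernel_side),
                            fan_in, rng)
        self.b = np.zeros(out_channels, dtype=DTYPE)

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}"
            )
        cols = im2col(x, self.k, self.k)
        wmat = self.W.reshape(self.out_channels, -1)
        y = cols @ wmat.T + self.b
        y = y.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)
        return y, (cols, x.shape)

    def backward(self, dy, cache):
        cols, xshape = cache
        n, _, h, w = xshape
        dym = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        wmat = self.W.reshape(self.out_channels, -1)
        dW = (dym.T @ cols).reshape(self.W.shape)
        db = dym.sum(axis=0)
        dcols = dym @ wmat
        dx = _col2im(dcols, xshape, self.k, self.k)
        return dx, {"W": dW, "b": db}


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache, {}


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; requires even spatial sides."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even sides, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        mask = xr == y[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5
        )
        return y, (mask, x.shape)

    def backward(self, dy, cache):
        mask, xshape = cache
        n, c, h, w = xshape
        dx = mask * dy[:, :, :, None, :, None]
        return dx.reshape(n, c, h, w), {}


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            return x, None
        if rng is None:
            raise ValueError("train-mode dropout needs an rng")
        keep = (rng.random(x.shape) >= self.rate).astype(x.dtype)
        scale = 1.0 / (1.0 - self.rate)
        return x * keep * scale, keep * scale

    def backward(self, dy, cache):
        if cache is None:
            return dy, {}
        return dy * cache, {}


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache):
        return dy.reshape(cache), {}


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        y = self.gamma[:, None, None] * xhat + self.beta[:, None, None]
        return y, (xhat, inv)

    def backward(self, dy, cache):
        xhat, inv = cache
        n_eff = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[:, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_eff
        ) * inv[:, None, None]
        return dx, {"gamma": dgamma, "beta": dbeta}


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{name}"] = p
        return out

    def forward(self, x, train=False, rng=None):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, train=train, rng=rng)
            caches.append(cache)
        return x, caches

    def backward(self, dy, caches):
        grads = {}
        for i in reversed(range(len(self.layers))):
            dy, g = self.layers[i].backward(dy, caches[i])
            for name, val in g.items():
                grads[f"{i}.{name}"] = val
        return dy, grads


class Adam:
    """Adam over a flat {name: array} parameter dict; updates in place."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, p in self.params.items():
            if k not in grads:
                continue
            g = grads[k].astype(p.dtype)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def save_params(path: str, params: dict) -> None:
    np.savez(path, **params)


def load_params(path: str, params: dict) -> None:
    """Load arrays into an existing parameter dict in place (shapes must match)."""
    with np.load(path) as data:
        for k, p in params.items():
            p[...] = data[k]
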