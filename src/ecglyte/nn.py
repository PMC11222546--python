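"""Minimal 1-D convolutional network framework in numpy.

Implements exactly what the model zoo needs — Conv1d (im2col), ReLU, average
pooling, dropout, residual blocks, linear layers, Adam, and the four training
losses — with explicit reverse-mode gradients. Everything is deterministic
given the seeds handed to the initializers and training loops.

Shapes: convolutional tensors are ``(batch, channels, length)``; features and
head outputs are ``(batch, dim)``. Parameters are float32.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "Linear",
    "ReLU",
    "AvgPool1d",
    "GlobalAvgPool",
    "Flatten",
    "Dropout",
    "Sequential",
    "ResidualBlock",
    "Network",
    "Adam",
    "softplus",
    "sigmoid",
    "mse_loss",
    "gaussian_nll_loss",
    "cross_entropy_loss",
    "binary_cross_entropy_loss",
]


def softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_out, d_in)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gy):
        self.dW += (gy.T @ self._x).astype(np.float32)
        self.db += gy.sum(axis=0).astype(np.float32)
        return (gy @ self.W).astype(np.float32)


class Conv1d(Layer):
    """1-D convolution with 'same'-style padding ((k-1)//2 each side) and stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = (kernel - 1) // 2
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = (rng.standard_normal((c_out, c_in * kernel)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_length(self, length: int) -> int:
        return (length + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train=False):
        b, c, n = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        win = win[:, :, :: self.stride, :]  # (B, C, L_out, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            b, -1, self.c_in * self.k
        )
        self._cols, self._n = cols, n
        y = cols @ self.W.T + self.b  # (B, L_out, C_out)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, gy):
        b, _, l_out = gy.shape
        g = np.ascontiguousarray(gy.transpose(0, 2, 1))  # (B, L_out, C_out)
        g2 = g.reshape(-1, g.shape[2])
        self.dW += (g2.T @ self._cols.reshape(g2.shape[0], -1)).astype(np.float32)
        self.db += g2.sum(axis=0).astype(np.float32)
        dcols = (g @ self.W).reshape(b, l_out, self.c_in, self.k)
        dcols = dcols.transpose(0, 2, 1, 3)  # (B, C_in, L_out, k)
        dxp = np.zeros((b, self.c_in, self._n + 2 * self.pad), dtype=np.float32)
        for j in range(self.k):
            dxp[:, :, j : j + self.stride * l_out : self.stride] += dcols[:, :, :, j]
        return dxp[:, :, self.pad : self.pad + self._n]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class AvgPool1d(Layer):
    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, train=False):
        b, c, n = x.shape
        if n % self.factor:
            raise ValueError(f"length {n} not divisible by pool factor {self.factor}")
        return x.reshape(b, c, n // self.factor, self.factor).mean(axis=3)

    def backward(self, gy):
        return np.repeat(gy / self.factor, self.factor, axis=2)


class GlobalAvgPool(Layer):
    """(B, C, L) -> (B, C) feature vector."""

    def forward(self, x, train=False):
        self._n = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None] / self._n, self._n, axis=2)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at rate 0 or in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class ResidualBlock(Layer):
    """conv-relu-conv with an additive skip; 1x1 conv on the skip when shapes change."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.conv1 = Conv1d(c_in, c_out, kernel, stride, rng)
        self.relu1 = ReLU()
        self.drop = Dropout(dropout, rng)
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, rng)
        self.relu_out = ReLU()
        if c_in != c_out or stride != 1:
            self.skip: Conv1d | None = Conv1d(c_in, c_out, 1, stride, rng)
        else:
            self.skip = None

    def params(self):
        layers = [self.conv1, self.conv2] + ([self.skip] if self.skip else [])
        return [p for l in layers for p in l.params()]

    def grads(self):
        layers = [self.conv1, self.conv2] + ([self.skip] if self.skip else [])
        return [g for l in layers for g in l.grads()]

    def forward(self, x, train=False):
        h = self.conv2.forward(
            self.drop.forward(self.relu1.forward(self.conv1.forward(x, train), train), train),
            train,
        )
        s = self.skip.forward(x, train) if self.skip else x
        return self.relu_out.forward(h + s, train)

    def backward(self, gy):
        g = self.relu_out.backward(gy)
        gs = self.skip.backward(g) if self.skip else g
        gh = self.conv1.backward(
            self.relu1.backward(self.drop.backward(self.conv2.backward(g)))
        )
        return gh + gs


class Network:
    """A feature-extracting backbone with one or more linear heads."""

    def __init__(self, backbone: Sequential, heads: list[Linear]):
        self.backbone = backbone
        self.heads = heads

    def params(self):
        return self.backbone.params() + [p for h in self.heads for p in h.params()]

    def grads(self):
        return self.backbone.grads() + [g for h in self.heads for g in h.grads()]

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0.0

    def forward(self, x, train=False):
        feat = self.backbone.forward(x.astype(np.float32), train=train)
        return feat, [h.forward(feat, train=train) for h in self.heads]

    def backward(self, head_grads):
        gfeat = None
        for h, gy in zip(self.heads, head_grads):
            g = h.backward(gy.astype(np.float32))
            gfeat = g if gfeat is None else gfeat + g
        self.backbone.backward(gfeat)

    def features(self, x) -> np.ndarray:
        return self.backbone.forward(x.astype(np.float32), train=False)

    # -- parameter snapshots -------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


# ----------------------------------------------------------------------------
# Losses: each returns (scalar value, list of gradients wrt the head outputs)
# ----------------------------------------------------------------------------

VAR_FLOOR = 1e-6  # variance positivity floor after softplus


def mse_loss(pred: np.ndarray, y: np.ndarray):
    r = pred.ravel().astype(float) - y.astype(float)
    n = r.size
    return float(np.mean(r**2)), [2.0 * r[:, None] / n]


def gaussian_nll_loss(mu: np.ndarray, raw_var: np.ndarray, y: np.ndarray):
    """Mean Gaussian NLL with variance = softplus(raw) + floor."""
    mu = mu.ravel().astype(float)
    raw = raw_var.ravel().astype(float)
    y = y.astype(float)
    var = softplus(raw) + VAR_FLOOR
    n = y.size
    resid = y - mu
    nll = float(np.mean(0.5 * np.log(2 * np.pi * var) + resid**2 / (2 * var)))
    dmu = (mu - y) / var / n
    dvar = 0.5 * (1.0 / var - resid**2 / var**2) / n
    draw = dvar * sigmoid(raw)
    return nll, [dmu[:, None], draw[:, None]]


def cross_entropy_loss(logits: np.ndarray, class_idx: np.ndarray):
    """Mean CE over a batch; ``class_idx`` is 0-based."""
    z = logits.astype(float)
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = z.shape[0]
    ce = float(-logp[np.arange(n), class_idx].mean())
    p = np.exp(logp)
    p[np.arange(n), class_idx] -= 1.0
    return ce, [p / n]

def binary_cross_entropy_loss(logits: np.ndarray, targets: np.ndarray):
    """Mean elementwise BCE with logits over an (n, k-1) threshold array."""
    z = logits.astype(float)
    t = targets.astype(float)
    loss = float(np.mean(softplus(z) - t * z))
    return loss, [(sigmoid(z) - t) / z.size]
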