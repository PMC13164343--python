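"""Minimal NumPy neural-network kit for the reference classifier.

Explicit forward/backward implementations of the handful of layers the
reference CNN needs (3x3 convolution via im2col, batch normalization,
ReLU, 2x2 max pooling, global average pooling, dropout, linear), plus an
AdamW optimizer with decoupled weight decay.  Single precision
throughout; everything is seeded and deterministic on one platform.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dropout",
    "Linear",
    "AdamW",
    "softmax",
]

DTYPE = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    def params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, via im2col."""

    def __init__(self, cin, cout, k=3, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.w = (rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k, self.cin, self.cout = k, cin, cout
        self.pad = k // 2

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def _cols(self, x):
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        self._shape = x.shape
        self._cols_cache = self._cols(x)
        out = self._cols_cache @ self.w + self.b
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = self._shape
        gmat = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.gw += self._cols_cache.T @ gmat
        self.gb += gmat.sum(axis=0)
        dcols = (gmat @ self.w.T).reshape(n, h, w, self.cin, self.k, self.k)
        p = self.pad
        dxp = np.zeros((n, self.cin, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(DTYPE)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        self.ggamma += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.gbeta += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        if not self._train:
            return g / self._std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
        sum_gx = (g * self._xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return (g - sum_g / m - self._xhat * sum_gx / m) / self._std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2, stride 2 (input spatial dims must be even)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        self._mask = r == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        g = grad[:, :, :, None, :, None] * self._mask
        return g.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dropout(Layer):
    def __init__(self, p=0.5, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(DTYPE)

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask.astype(DTYPE)


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = (rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.w.T


class AdamW:
    """Adam with decoupled weight decay (biases/BN params included for
    simplicity; the reference model is insensitive to this detail)."""

    def __init__(self, params, lr=3e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)
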