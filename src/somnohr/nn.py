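"""Minimal 1-D convolutional network engine with explicit backpropagation.

Implements exactly the pieces the staging model needs — dilated same-padded
1-D convolutions, ReLU, global average pooling, dense layers, softmax
cross-entropy and Adam — as plain numpy with hand-derived gradients.
Convolutions run through a strided sliding-window view plus einsum, which
keeps desk-scale training (tens of thousands of parameters, a few dozen
recordings) in seconds-to-minutes territory on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv1d", "Linear", "ReLU", "softmax",
           "cross_entropy_with_logits", "Adam"]


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value
        self.g = np.zeros_like(value)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / max(1, fan_in))


class Conv1d:
    """Same-padded 1-D convolution, optional dilation.  x: (N, C, T)."""

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.d = k, dilation
        self.W = Param(he_init(rng, (c_out, c_in, k), c_in * k))
        self.b = Param(np.zeros(c_out))
        ke = (k - 1) * dilation + 1
        self.pad_l = (ke - 1) // 2
        self.pad_r = ke - 1 - self.pad_l

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._T = x.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        view = np.lib.stride_tricks.sliding_window_view(
            xp, (self.k - 1) * self.d + 1, axis=2)
        self._cols = view[..., :: self.d] if self.d > 1 else view  # (N,C,T,k)
        self._xp_shape = xp.shape
        return np.einsum("nctk,fck->nft", self._cols, self.W.v,
                         optimize=True) + self.b.v[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += np.einsum("nft,nctk->fck", dy, self._cols, optimize=True)
        self.b.g += dy.sum(axis=(0, 2))
        dxp = np.zeros(self._xp_shape)
        T = self._T
        for j in range(self.k):
            off = j * self.d
            dxp[:, :, off:off + T] += np.einsum(
                "nft,fc->nct", dy, self.W.v[:, :, j], optimize=True)
        return dxp[:, :, self.pad_l:self.pad_l + T]


class Linear:
    """Dense layer.  x: (N, C)."""

    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(he_init(rng, (c_out, c_in), c_in))
        self.b = Param(np.zeros(c_out))

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.v.T + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += dy.T @ self._x
        self.b.g += dy.sum(axis=0)
        return dy @ self.W.v


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._m = x > 0
        return x * self._m

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._m


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray, axis: int = -1) -> np.ndarray:
    """Gradient through y = softmax(z): dz = p * (dp - sum(dp * p))."""
    return p * (dp - np.sum(dp * p, axis=axis, keepdims=True))


def cross_entropy_with_logits(logits: np.ndarray, targets: np.ndarray,
                              class_weights: np.ndarray | None = None):
    """Mean weighted cross-entropy.  logits: (N, K); targets: (N,) ints.

    Returns (loss, dlogits) with dlogits already averaged."""
    n, k = logits.shape
    p = softmax(logits, axis=1)
    w = np.ones(n) if class_weights is None else class_weights[targets]
    logp = logits - np.max(logits, axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    loss = float(-(w * logp[np.arange(n), targets]).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.v = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            v[...] = self.b2 * v + (1 - self.b2) * p.g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.v -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
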