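"""Minimal NumPy neural-network layers with hand-written backpropagation.

Just enough machinery for the measurement-conditioned adversarial
reconstructor: dense and strided (de)convolution layers via im2col/col2im,
batch normalization, dropout, leaky-ReLU and sigmoid activations, a
torch-compatible Adam optimizer (L2 weight decay added to the gradient), and
cosine annealing with warm restarts.  Every layer implements ``forward`` and
``backward`` with explicit caches; analytic gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "BatchNorm2d",
    "Conv2d",
    "ConvTranspose2d",
    "CosineAnnealingWarmRestarts",
    "Dense",
    "Dropout",
    "LeakyReLU",
    "Param",
    "Sigmoid",
    "bce_loss",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def set_training(self, flag: bool) -> None:
        self.training = flag


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_he_init(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    """(B, C, H, W) -> columns (B, Ho*Wo, C*k*k) using stride tricks."""
    B, C, H, W = x.shape
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    sB, sC, sH, sW = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, Ho, Wo, k, k),
        strides=(sB, sC, sH * s, sW * s, sH, sW), writeable=False)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k), (Ho, Wo)


def _col2im(cols: np.ndarray, x_shape, k: int, s: int, p: int):
    """Scatter-add adjoint of _im2col."""
    B, C, H, W = x_shape
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    xp = np.zeros((B, C, H + 2 * p, W + 2 * p))
    c6 = cols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += c6[:, :, :, :, ki, kj]
    return xp[:, :, p:p + H, p:p + W]


class Conv2d(Module):
    """Strided convolution; default k=4, s=2, p=1 halves the spatial size."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1):
        self.k, self.s, self.p = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_he_init(rng, (c_in * k * k, c_out), c_in * k * k))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        cols, (Ho, Wo) = _im2col(x, self.k, self.s, self.p)
        y = cols @ self.W.value + self.b.value
        self._cache = (cols, x.shape, Ho, Wo)
        return y.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, Ho, Wo)

    def backward(self, dy):
        cols, x_shape, Ho, Wo = self._cache
        dyf = dy.reshape(dy.shape[0], self.c_out, Ho * Wo).transpose(0, 2, 1)
        self.W.grad += np.einsum("bpq,bpo->qo", cols, dyf)
        self.b.grad += dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W.value.T
        return _col2im(dcols, x_shape, self.k, self.s, self.p)


class ConvTranspose2d(Module):
    """Strided transposed convolution; default k=4, s=2, p=1 doubles sizes.

    Implemented as the adjoint of :class:`Conv2d`: forward scatters through
    col2im, backward gathers through im2col with the same kernel.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1):
        self.k, self.s, self.p = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_he_init(rng, (c_out * k * k, c_in), c_in * k * k))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _out_shape(self, x):
        B, _, H, W = x.shape
        return (B, self.c_out,
                self.s * (H - 1) + self.k - 2 * self.p,
                self.s * (W - 1) + self.k - 2 * self.p)

    def forward(self, x):
        B, C, H, W = x.shape
        out_shape = self._out_shape(x)
        xf = x.reshape(B, C, H * W).transpose(0, 2, 1)  # (B, HW, c_in)
        cols = xf @ self.W.value.T  # (B, HW, c_out*k*k)
        y = _col2im(cols, out_shape, self.k, self.s, self.p)
        y += self.b.value[None, :, None, None]
        self._cache = (xf, x.shape, out_shape)
        return y

    def backward(self, dy):
        xf, x_shape, out_shape = self._cache
        dcols, _ = _im2col(dy, self.k, self.s, self.p)  # (B, HW, c_out*k*k)
        self.W.grad += np.einsum("bpq,bpc->qc", dcols, xf)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxf = dcols @ self.W.value  # (B, HW, c_in)
        B, C, H, W = x_shape
        return dxf.transpose(0, 2, 1).reshape(B, C, H, W)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if self.training:
            dxhat = dy * g
            term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
            return term * inv[None, :, None, None]
        return dy * g * inv[None, :, None, None]


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Module):
    """50% dropout by default; stays active at inference (it replaces the
    latent noise vector of a classic cGAN), driven by a reseedable rng."""

    def __init__(self, p: float = 0.5, seed: int = 0):
        self.p = p
        self.rng = np.random.default_rng(seed)
        self._mask = None

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        self._mask = self.rng.random(x.shape) >= self.p
        return x * self._mask / (1.0 - self.p)

    def backward(self, dy):
        return dy * self._mask / (1.0 - self.p)


def bce_loss(pred: np.ndarray, target: float, eps: float = 1e-7):
    """Binary cross entropy against a constant target; returns (loss, dpred).

    ``pred`` must already be sigmoid outputs in (0, 1)."""
    if np.any(pred <= 0.0) or np.any(pred >= 1.0):
        raise ValueError("BCE input must lie strictly in (0, 1); missing sigmoid?")
    p = np.clip(pred, eps, 1.0 - eps)
    loss = -np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))
    dp = (-(target / p) + (1.0 - target) / (1.0 - p)) / p.size
    return float(loss), dp


class Adam:
    """Adam with torch-style coupled L2 weight decay (grad += wd * w)."""

    def __init__(self, params: list[Param], lr: float, betas=(0.5, 0.999),
                 weight_decay: float = 0.0, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.wd = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad + self.wd * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CosineAnnealingWarmRestarts:
    """lr(t) = lr0 * (1 + cos(pi * T_cur / T_i)) / 2, T_i growing by T_mult
    at each restart; stepped once per iteration."""

    def __init__(self, optimizer: Adam, T0: int, T_mult: int = 2,
                 eta_min: float = 0.0):
        self.opt = optimizer
        self.base_lr = optimizer.lr
        self.T_i = T0
        self.T_mult = T_mult
        self.T_cur = 0
        self.eta_min = eta_min
        self._apply()

    def _apply(self):
        self.opt.lr = self.eta_min + (self.base_lr - self.eta_min) * \
            (1 + np.cos(np.pi * self.T_cur / self.T_i)) / 2

    def step(self):
        self.T_cur += 1
        if self.T_cur >= self.T_i:
            self.T_cur = 0
            self.T_i *= self.T_mult
        self._apply()

    @property
    def lr(self):
        return self.opt.lr
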