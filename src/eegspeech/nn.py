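"""A compact numpy CNN engine for EEG-shaped inputs.

Implements exactly the layers the three EEG decoding architectures
need — grouped 2-D convolution (stride 1), batch normalization, ELU /
ReLU / leaky-ReLU / square activations, clamped log, mean/max pooling
along time, dropout, dense — with hand-derived backward passes and an
ADAM optimizer.  Gradients are verified against central finite
differences in the test suite.

Inputs are (N, C, H, W) with H = EEG channels and W = time samples; the
raw input has C = 1.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "Activation",
    "LogAct",
    "PoolTime",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "nll_from_logits",
    "ce_from_logits",
    "LOSSES",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when training produces a non-finite loss."""


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list:
        """List of (param_array, grad_array) pairs; updated in place."""
        return []


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, OH*OW) patch matrix, stride 1."""
    n, c, h, w = x.shape
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,OH,OW,kh,kw)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int) -> np.ndarray:
    """Adjoint of _im2col (scatter-add patches back)."""
    n, c, h, w = x_shape
    oh, ow = h - kh + 1, w - kw + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    x = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + oh, j : j + ow] += cols[:, :, i, j]
    return x


class Conv2d(Layer):
    """Grouped 2-D convolution, stride 1, optional 'same' padding.

    groups == in_channels gives a depthwise convolution.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple,
        rng: np.random.Generator,
        groups: int = 1,
        bias: bool = True,
        padding: str = "valid",
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.cin, self.cout, self.groups = in_channels, out_channels, groups
        self.kh, self.kw = kernel
        self.padding = padding
        cin_g = in_channels // groups
        fan_in = cin_g * self.kh * self.kw
        fan_out = (out_channels // groups) * self.kh * self.kw
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(-limit, limit, (out_channels, cin_g, self.kh, self.kw))
        self.dw = np.zeros_like(self.w)
        self.b = np.zeros(out_channels) if bias else None
        self.db = np.zeros(out_channels) if bias else None

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0, 0, 0)
        ph0, ph1 = (self.kh - 1) // 2, self.kh // 2
        pw0, pw1 = (self.kw - 1) // 2, self.kw // 2
        return (
            np.pad(x, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1))),
            (ph0, ph1, pw0, pw1),
        )

    def forward(self, x, training):
        xp, self._padspec = self._pad(x)
        self._x_shape = xp.shape
        n = x.shape[0]
        oh, ow = xp.shape[2] - self.kh + 1, xp.shape[3] - self.kw + 1
        cin_g = self.cin // self.groups
        cout_g = self.cout // self.groups
        cols = _im2col(xp, self.kh, self.kw)  # (N, C*kh*kw, L)
        self._cols = cols
        k = cin_g * self.kh * self.kw
        out = np.empty((n, self.cout, oh * ow))
        wmat = self.w.reshape(self.cout, k)
        for g in range(self.groups):
            cg = cols[:, g * k : (g + 1) * k, :]
            wg = wmat[g * cout_g : (g + 1) * cout_g]
            out[:, g * cout_g : (g + 1) * cout_g, :] = np.einsum(
                "ok,nkl->nol", wg, cg, optimize=True
            )
        if self.b is not None:
            out += self.b[None, :, None]
        return out.reshape(n, self.cout, oh, ow)

    def backward(self, grad):
        n, _, oh, ow = grad.shape
        g2 = grad.reshape(n, self.cout, oh * ow)
        cin_g = self.cin // self.groups
        cout_g = self.cout // self.groups
        k = cin_g * self.kh * self.kw
        dcols = np.empty_like(self._cols)
        dwmat = np.zeros((self.cout, k))
        wmat = self.w.reshape(self.cout, k)
        for g in range(self.groups):
            cg = self._cols[:, g * k : (g + 1) * k, :]
            gg = g2[:, g * cout_g : (g + 1) * cout_g, :]
            wg = wmat[g * cout_g : (g + 1) * cout_g]
            dwmat[g * cout_g : (g + 1) * cout_g] = np.einsum(
                "nol,nkl->ok", gg, cg, optimize=True
            )
            dcols[:, g * k : (g + 1) * k, :] = np.einsum(
                "ok,nol->nkl", wg, gg, optimize=True
            )
        self.dw += dwmat.reshape(self.w.shape)
        if self.b is not None:
            self.db += g2.sum(axis=(0, 2))
        dxp = _col2im(dcols, self._x_shape, self.kh, self.kw)
        ph0, ph1, pw0, pw1 = self._padspec
        h, w = self._x_shape[2] - ph0 - ph1, self._x_shape[3] - pw0 - pw1
        return dxp[:, :, ph0 : ph0 + h, pw0 : pw0 + w]

    def params(self):
        p = [(self.w, self.dw)]
        if self.b is not None:
            p.append((self.b, self.db))
        return p

    def n_parameters(self) -> int:
        return self.w.size + (self.b.size if self.b is not None else 0)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._training = training
        return self.gamma[None, :, None, None] * self._xhat + self.beta[
            None, :, None, None
        ]

    def backward(self, grad):
        self.dgamma += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        if not self._training:
            return g / self._std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dxhat = g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std[None, :, None, None]
        return dx

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def n_parameters(self) -> int:
        return self.gamma.size + self.beta.size


class Activation(Layer):
    """ELU / ReLU / leaky ReLU / square, selected by name."""

    VALID = ("elu", "relu", "leaky_relu", "square")

    def __init__(self, name: str, leaky_slope: float = 0.01):
        if name not in self.VALID:
            raise ValueError(
                f"unknown activation {name!r}; valid: {list(self.VALID)}"
            )
        self.name = name
        self.slope = leaky_slope

    def forward(self, x, training):
        self._x = x
        if self.name == "elu":
            self._out = np.where(x > 0, x, np.expm1(np.clip(x, None, 50.0)))
            return self._out
        if self.name == "relu":
            return np.maximum(x, 0)
        if self.name == "leaky_relu":
            return np.where(x > 0, x, self.slope * x)
        return x**2

    def backward(self, grad):
        x = self._x
        if self.name == "elu":
            return grad * np.where(x > 0, 1.0, self._out + 1.0)
        if self.name == "relu":
            return grad * (x > 0)
        if self.name == "leaky_relu":
            return grad * np.where(x > 0, 1.0, self.slope)
        return grad * 2 * x


class LogAct(Layer):
    """log(max(x, eps)); gradient zero below the clamp."""

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x, training):
        self._x = x
        return np.log(np.maximum(x, self.eps))

    def backward(self, grad):
        return grad * (self._x > self.eps) / np.maximum(self._x, self.eps)


class PoolTime(Layer):
    """Mean or max pooling along the time (W) axis."""

    def __init__(self, size: int, stride: int, mode: str = "mean"):
        if mode not in ("mean", "max"):
            raise ValueError(f"unknown pool mode {mode!r}")
        self.size, self.stride, self.mode = size, stride, mode

    def forward(self, x, training):
        self._x_shape = x.shape
        win = sliding_window_view(x, self.size, axis=3)[:, :, :, :: self.stride, :]
        if self.mode == "mean":
            return win.mean(axis=-1)
        self._win = win
        self._arg = win.argmax(axis=-1)
        return win.max(axis=-1)

    def backward(self, grad):
        dx = np.zeros(self._x_shape, dtype=grad.dtype)
        n_out = grad.shape[3]
        if self.mode == "mean":
            g = grad / self.size
            for o in range(n_out):
                s = o * self.stride
                dx[:, :, :, s : s + self.size] += g[:, :, :, o : o + 1]
            return dx
        n, c, h, _ = grad.shape
        ni, ci, hi = np.ix_(range(n), range(c), range(h))
        for o in range(n_out):
            s = o * self.stride
            idx = self._arg[:, :, :, o]
            np.add.at(dx, (ni, ci, hi, s + idx), grad[:, :, :, o])
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def n_parameters(self) -> int:
        return self.w.size + self.b.size


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())


class Adam:
    def __init__(
        self,
        params: list,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def nll_from_logits(logits: np.ndarray, y: np.ndarray):
    """Mean negative log-likelihood of the true class; returns
    (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = _softmax(logits)
    logp = np.log(np.maximum(p[np.arange(n), y], 1e-12))
    loss = -logp.mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def ce_from_logits(logits: np.ndarray, y: np.ndarray, eps: float = 1e-12):
    """Summed per-class binary cross-entropy of the softmax output
    against one-hot targets, averaged over the batch."""
    n, k = logits.shape
    p = _softmax(logits)
    pc = np.clip(p, eps, 1 - eps)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    loss = -np.mean(
        np.sum(onehot * np.log(pc) + (1 - onehot) * np.log(1 - pc), axis=1)
    )
    dldp = -(onehot / pc - (1 - onehot) / (1 - pc)) / n
    # chain through the softmax Jacobian
    grad = p * (dldp - np.sum(dldp * p, axis=1, keepdims=True))
    return loss, grad


LOSSES = {"nll": nll_from_logits, "ce": ce_from_logits}
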