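"""NumPy neural-network primitives with reverse-mode gradients.

Everything the classifier needs is built here from the defining equations:
2-D convolution (same padding, centered odd kernel), depthwise convolution,
batch normalization, Swish/ReLU/LeakyReLU activations, squeeze-and-
excitation channel gating, the inverted-residual (MBConv) block, an LSTM
and a dense head. Each layer caches what its backward pass needs; gradients
accumulate into ``Param.grad``.

Tensor layout is NHWC: ``x[batch, row, col, channel]``.

Convolution semantics (the reference definition the tests' loop oracle also
implements): with kernel size (M, N) and stride s,

    y(i, j, k) = sum_{m,n,c} x~(i*s + m - M//2, j*s + n - N//2, c) * Q(m, n, c, k) + B(k)

where ``x~`` is the input zero-extended outside its support and the output
spatial side is ``ceil(input_side / s)``.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "Activation",
    "swish",
    "SEBlock",
    "MBConv",
    "LSTM",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer: forward caches, backward returns the input gradient."""

    def __init__(self) -> None:
        self._params: list[Param] = []

    def add_param(self, value: np.ndarray, name: str = "") -> Param:
        p = Param(value, name)
        self._params.append(p)
        return p

    @property
    def params(self) -> list[Param]:
        return list(self._params)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad_amounts(size: int, k: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for centered same-padding."""
    out = math.ceil(size / stride)
    before = k // 2
    after = max(0, (out - 1) * stride + k - size - before)
    return out, before, after


class Conv2d(Layer):
    """Full 2-D convolution: weights Q(m, n, c, k), bias B(k)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        rng: Optional[np.random.Generator] = None,
        bias: bool = True,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        M = kernel_size
        fan_in = M * M * in_channels
        scale = math.sqrt(2.0 / fan_in)
        self.Q = self.add_param(rng.normal(0.0, scale, (M, M, in_channels, out_channels)), "Q")
        self.B = self.add_param(np.zeros(out_channels), "B") if bias else None
        self.kernel_size = M
        self.stride = stride
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[3] != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[3]}, kernel expects {self.in_channels}"
            )
        Bn, H, W, C = x.shape
        M = self.kernel_size
        s = self.stride
        Ho, pt, pb = _pad_amounts(H, M, s)
        Wo, pl, pr = _pad_amounts(W, M, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        out = np.zeros((Bn, Ho, Wo, self.out_channels))
        Q = self.Q.value
        for m in range(M):
            for n in range(M):
                xs = xp[:, m : m + (Ho - 1) * s + 1 : s, n : n + (Wo - 1) * s + 1 : s, :]
                out += xs @ Q[m, n]  # (B,Ho,Wo,C) @ (C,K)
        if self.B is not None:
            out += self.B.value
        self._cache = (xp, x.shape, (Ho, Wo, pt, pl))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, xshape, (Ho, Wo, pt, pl) = self._cache
        Bn, H, W, C = xshape
        M, s = self.kernel_size, self.stride
        Q = self.Q.value
        dxp = np.zeros_like(xp)
        for m in range(M):
            for n in range(M):
                sl_r = slice(m, m + (Ho - 1) * s + 1, s)
                sl_c = slice(n, n + (Wo - 1) * s + 1, s)
                xs = xp[:, sl_r, sl_c, :]
                self.Q.grad[m, n] += np.einsum("bijc,bijk->ck", xs, grad)
                dxp[:, sl_r, sl_c, :] += grad @ Q[m, n].T
        if self.B is not None:
            self.B.grad += grad.sum(axis=(0, 1, 2))
        return dxp[:, pt : pt + H, pl : pl + W, :]


class DepthwiseConv2d(Layer):
    """Per-channel convolution: weights W_dw(m, n, c); channels never mix."""

    def __init__(
        self,
        channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        M = kernel_size
        scale = math.sqrt(2.0 / (M * M))
        self.W = self.add_param(rng.normal(0.0, scale, (M, M, channels)), "W_dw")
        self.kernel_size = M
        self.stride = stride
        self.channels = channels

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[3] != self.channels:
            raise ValueError("channel mismatch in depthwise convolution")
        Bn, H, W_, C = x.shape
        M, s = self.kernel_size, self.stride
        Ho, pt, pb = _pad_amounts(H, M, s)
        Wo, pl, pr = _pad_amounts(W_, M, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        out = np.zeros((Bn, Ho, Wo, C))
        Wv = self.W.value
        for m in range(M):
            for n in range(M):
                xs = xp[:, m : m + (Ho - 1) * s + 1 : s, n : n + (Wo - 1) * s + 1 : s, :]
                out += xs * Wv[m, n]
        self._cache = (xp, x.shape, (Ho, Wo, pt, pl))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, xshape, (Ho, Wo, pt, pl) = self._cache
        Bn, H, W_, C = xshape
        M, s = self.kernel_size, self.stride
        Wv = self.W.value
        dxp = np.zeros_like(xp)
        for m in range(M):
            for n in range(M):
                sl_r = slice(m, m + (Ho - 1) * s + 1, s)
                sl_c = slice(n, n + (Wo - 1) * s + 1, s)
                xs = xp[:, sl_r, sl_c, :]
                self.W.grad[m, n] += (xs * grad).sum(axis=(0, 1, 2))
                dxp[:, sl_r, sl_c, :] += grad * Wv[m, n]
        return dxp[:, pt : pt + H, pl : pl + W_, :]


class BatchNorm2d(Layer):
    """Per-channel normalization over (batch, row, col) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param(np.ones(channels), "gamma")
        self.beta = self.add_param(np.zeros(channels), "beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape, train)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape, train = self._cache
        n = np.prod([shape[a] for a in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not train:
            return g * inv
        return (
            inv / n * (n * g - g.sum(axis=axes) - xhat * (g * xhat).sum(axis=axes))
        )


def _sigmoid(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v, dtype=float)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def swish(v):
    """Swish activation: v * sigmoid(v)."""
    v = np.asarray(v, dtype=float)
    return v * _sigmoid(v)


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "swish": (
        swish,
        lambda v: (lambda s: s + v * s * (1 - s))(_sigmoid(np.asarray(v, dtype=float))),
    ),
    "relu": (lambda v: np.maximum(v, 0.0), lambda v: (v > 0).astype(float)),
    "leaky_relu": (
        lambda v: np.where(v > 0, v, 0.01 * v),
        lambda v: np.where(v > 0, 1.0, 0.01),
    ),
    "sigmoid": (_sigmoid, lambda v: (lambda s: s * (1 - s))(_sigmoid(v))),
}


class Activation(Layer):
    def __init__(self, kind: str = "swish"):
        super().__init__()
        if kind not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        self.fn, self.dfn = _ACTIVATIONS[kind]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x
        return self.fn(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self.dfn(self._cache)


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    z(c) = mean over (row, col) of x(., ., c); the excitation network maps z
    through a reduction layer (width max(1, C // r)), an activation, an
    expansion layer and a sigmoid; the gate multiplies each channel.
    """

    def __init__(
        self,
        channels: int,
        reduction: int = 4,
        activation: str = "swish",
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.W1 = self.add_param(rng.normal(0, math.sqrt(2.0 / channels), (channels, hidden)), "W1")
        self.b1 = self.add_param(np.zeros(hidden), "b1")
        self.W2 = self.add_param(rng.normal(0, math.sqrt(2.0 / hidden), (hidden, channels)), "W2")
        self.b2 = self.add_param(np.zeros(channels), "b2")
        self.act = Activation(activation)
        self.channels = channels

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[3] != self.channels:
            raise ValueError("channel mismatch in SE block")
        Bn, H, W, C = x.shape
        z = x.mean(axis=(1, 2))  # (B, C) global average pool
        h_pre = z @ self.W1.value + self.b1.value
        h = self.act.forward(h_pre, train)
        g_pre = h @ self.W2.value + self.b2.value
        gate = _sigmoid(g_pre)
        self._cache = (x, z, h, gate)
        return x * gate[:, None, None, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, h, gate = self._cache
        Bn, H, W, C = x.shape
        dx = grad * gate[:, None, None, :]
        dgate = (grad * x).sum(axis=(1, 2))  # (B, C)
        dg_pre = dgate * gate * (1 - gate)
        self.W2.grad += h.T @ dg_pre
        self.b2.grad += dg_pre.sum(axis=0)
        dh = dg_pre @ self.W2.value.T
        dh_pre = self.act.backward(dh)
        self.W1.grad += z.T @ dh_pre
        self.b1.grad += dh_pre.sum(axis=0)
        dz = dh_pre @ self.W1.value.T
        dx += dz[:, None, None, :] / (H * W)
        return dx


class _Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class MBConv(Layer):
    """Inverted-residual block: expand -> depthwise -> SE -> project.

    Pointwise (1x1) expansion by factor t, 3x3 depthwise convolution at the
    block stride, squeeze-and-excitation gating, pointwise projection; batch
    norm follows each convolution, the activation follows the first two
    norms, and the input is added back when the stride is 1 and the channel
    counts match.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        expansion: int = 4,
        stride: int = 1,
        se_reduction: int = 4,
        activation: str = "swish",
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng(0)
        mid = in_channels * expansion
        layers: list[Layer] = []
        if expansion != 1:
            layers += [
                Conv2d(in_channels, mid, kernel_size=1, rng=rng, bias=False),
                BatchNorm2d(mid),
                Activation(activation),
            ]
        layers += [
            DepthwiseConv2d(mid, kernel_size=3, stride=stride, rng=rng),
            BatchNorm2d(mid),
            Activation(activation),
            SEBlock(mid, reduction=se_reduction, activation=activation, rng=rng),
            Conv2d(mid, out_channels, kernel_size=1, rng=rng, bias=False),
            BatchNorm2d(out_channels),
        ]
        self.body = _Sequential(layers)
        self.use_residual = stride == 1 and in_channels == out_channels

    @property
    def params(self) -> list[Param]:
        return self.body.params

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = self.body.forward(x, train)
        return out + x if self.use_residual else out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = self.body.backward(grad)
        return dx + grad if self.use_residual else dx


class LSTM(Layer):
    """Single-layer LSTM over (batch, time, features); returns final hidden state.

    Gates follow the standard formulation (input, forget, cell, output) with
    the forget-gate bias initialized to 1.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        D, U = input_size, hidden_size
        scale = math.sqrt(1.0 / max(D, 1))
        self.Wx = self.add_param(rng.normal(0, scale, (D, 4 * U)), "Wx")
        self.Wh = self.add_param(rng.normal(0, math.sqrt(1.0 / U), (U, 4 * U)), "Wh")
        b = np.zeros(4 * U)
        b[U : 2 * U] = 1.0  # forget-gate bias
        self.b = self.add_param(b, "b")
        self.hidden_size = U
        self.input_size = D

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        Bn, T, D = x.shape
        U = self.hidden_size
        h = np.zeros((Bn, U))
        c = np.zeros((Bn, U))
        cache = []
        for t in range(T):
            gates = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(gates[:, :U])
            f = _sigmoid(gates[:, U : 2 * U])
            g = np.tanh(gates[:, 2 * U : 3 * U])
            o = _sigmoid(gates[:, 3 * U :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((x[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        self._cache = (cache, x.shape)
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cache, (Bn, T, D) = self._cache
        U = self.hidden_size
        dx = np.zeros((Bn, T, D))
        dh = grad.copy()
        dc = np.zeros((Bn, U))
        for t in reversed(range(T)):
            xt, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.Wx.grad += xt.T @ dgates
            self.Wh.grad += h_prev.T @ dgates
            self.b.grad += dgates.sum(axis=0)
            dx[:, t] = dgates @ self.Wx.value.T
            dh = dgates @ self.Wh.value.T
            dc = dc * f
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / in_features)
        self.W = self.add_param(rng.normal(0, scale, (in_features, out_features)), "W")
        self.b = self.add_param(np.zeros(out_features), "b")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns (loss, gradient w.r.t. logits).
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
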