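"""Minimal convolutional-network engine on numpy with manual backprop.

Implements exactly the pieces the hologram-to-phase translator needs:
strided 2-D convolution and transposed convolution (im2col + matmul),
batch normalization, LeakyReLU/ReLU/Tanh/Sigmoid, dropout, and Adam.
Tensors are (batch, channels, height, width) float64 arrays. Every layer
caches what its own backward pass needs; call forward then backward in
matching order. Gradients accumulate into ``Parameter.grad`` until the
optimizer's ``zero_grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Adam",
]


class Parameter:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


# -- functional conv primitives ---------------------------------------------


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Padded input (B,C,Hp,Wp) -> patch matrix (B,Ho,Wo,C,k,k)."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv_fwd(x, W, stride: int, pad: int):
    """Correlation forward pass; returns (out, cols) with cols cached for grads."""
    B = x.shape[0]
    O, C, k, _ = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, k, stride)  # (B, Ho, Wo, C, k, k)
    Ho, Wo = cols.shape[1], cols.shape[2]
    out = cols.reshape(B, Ho * Wo, C * k * k) @ W.reshape(O, -1).T
    return out.transpose(0, 2, 1).reshape(B, O, Ho, Wo), cols


def conv_bwd_weight(cols: np.ndarray, dout: np.ndarray) -> np.ndarray:
    B, O, Ho, Wo = dout.shape
    dW = np.tensordot(
        dout.reshape(B, O, Ho * Wo),
        cols.reshape(B, Ho * Wo, -1),
        axes=([0, 2], [0, 1]),
    )
    k = cols.shape[-1]
    return dW.reshape(O, cols.shape[3], k, k)


def _dilate(x: np.ndarray, stride: int) -> np.ndarray:
    if stride == 1:
        return x
    B, C, H, W = x.shape
    out = np.zeros((B, C, (H - 1) * stride + 1, (W - 1) * stride + 1), dtype=x.dtype)
    out[:, :, ::stride, ::stride] = x
    return out


def conv_bwd_input(dout, W, stride: int, pad: int, in_hw: tuple[int, int]):
    """Gradient w.r.t. the conv input; also the forward map of a transposed conv."""
    k = W.shape[2]
    d = _dilate(dout, stride)
    Wf = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    full, _ = conv_fwd(d, Wf, 1, k - 1 - pad)
    return full[:, :, : in_hw[0], : in_hw[1]]


# -- layers ------------------------------------------------------------------


def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator, name: str = "conv"):
        self.stride, self.pad = stride, pad
        self.W = Parameter(f"{name}.W", _he_init(rng, (out_ch, in_ch, kernel, kernel)))
        self.b = Parameter(f"{name}.b", np.zeros(out_ch))
        self._cols = None
        self._in_hw = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training: bool = True):
        self._in_hw = x.shape[2:]
        out, self._cols = conv_fwd(x, self.W.value, self.stride, self.pad)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout):
        self.W.grad += conv_bwd_weight(self._cols, dout)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dx = conv_bwd_input(dout, self.W.value, self.stride, self.pad, self._in_hw)
        self._cols = None
        return dx


class ConvTranspose2d:
    """Transposed convolution; the exact adjoint of Conv2d with same geometry."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator, name: str = "convT"):
        self.stride, self.pad, self.kernel = stride, pad, kernel
        # stored in the equivalent-conv orientation: (in_ch, out_ch, k, k)
        self.W = Parameter(f"{name}.W", _he_init(rng, (in_ch, out_ch, kernel, kernel)))
        self.b = Parameter(f"{name}.b", np.zeros(out_ch))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def out_hw(self, in_hw: tuple[int, int]) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return ((in_hw[0] - 1) * s - 2 * p + k, (in_hw[1] - 1) * s - 2 * p + k)

    def forward(self, x, training: bool = True):
        self._x = x
        out = conv_bwd_input(x, self.W.value, self.stride, self.pad, self.out_hw(x.shape[2:]))
        return out + self.b.value[None, :, None, None]

    def backward(self, dout):
        dx, cols = conv_fwd(dout, self.W.value, self.stride, self.pad)
        self.W.grad += conv_bwd_weight(cols, self._x)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        self._x = None
        return dx


class BatchNorm2d:
    """Batch normalization over (batch, height, width) per channel.

    Batch statistics are used in both training and inference (with batch
    size 1 this behaves like instance normalization, the standard practice
    for this model family); running averages are tracked for completeness.
    """

    def __init__(self, channels: int, name: str = "bn", eps: float = 1e-5,
                 momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training: bool = True):
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        if training:
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        self._cache = None
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        mean_dxhat = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return inv[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x, training: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x, training: bool = True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x, training: bool = True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout:
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x, training: bool = True):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Adam:
    """Adam optimizer with the GAN-customary beta1 = 0.5."""

    def __init__(self, params: list[Parameter], lr: float = 0.002,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
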