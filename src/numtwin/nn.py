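"""Minimal numpy neural-network core.

Just the pieces the gain-modulated recurrent network needs: im2col
convolutions, normalization-only (frozen-affine) batch norm, the gain-scaled
rectifier ``y = G * max(0, x)``, 2x2 max pooling, global average pooling, a
linear readout, softmax cross-entropy, and Adam.  Every layer implements an
explicit ``backward``; correctness is checked against finite differences in
the test suite.

Layers return ``(output, cache)`` and take the cache back in ``backward`` so
that a layer with shared weights (the recurrent convolution) can be applied
several times within one forward pass.  Input convolutions may skip the input
gradient (nothing upstream to train); all other convolutions are stride-1
"same" so the input gradient is itself a convolution with the flipped,
transposed kernel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)
        self.name = name


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, C*k*k, L) patch matrix and output extent."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo, _, _ = win.shape
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


class Conv2d:
    """Bias-free 2D convolution (batch norm follows every instance)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 input_grad: bool = True, dtype=np.float32) -> None:
        if pad is None:
            pad = k // 2
        if stride != 1 and input_grad:
            raise ValueError("input gradient implemented for stride-1 only")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        self.input_grad = input_grad
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))  # He fan-in
        w = rng.normal(0.0, std, size=(cout, cin * k * k)).astype(dtype)
        self.weight = Param(w, "conv.weight")

    @property
    def params(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray):
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        y = np.matmul(self.weight.value, cols)
        return y.reshape(x.shape[0], self.cout, ho, wo), cols

    def backward(self, dy: np.ndarray, cache) -> np.ndarray | None:
        cols = cache
        n, _, ho, wo = dy.shape
        dyf = dy.reshape(n, self.cout, ho * wo)
        self.weight.grad += np.einsum("ncl,nkl->ck", dyf, cols, optimize=True)
        if not self.input_grad:
            return None
        # stride-1 same conv: dx = dy (*) flip(W)^T
        w = self.weight.value.reshape(self.cout, self.cin, self.k, self.k)
        w_t = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        w_t = np.ascontiguousarray(w_t).reshape(self.cin, -1)
        cols_dy, (h2, w2) = _im2col(dy, self.k, 1, self.k - 1 - self.pad)
        dx = np.matmul(w_t, cols_dy)
        return dx.reshape(n, self.cin, h2, w2)


class BatchNorm2d:
    """Per-channel normalization with frozen (absent) affine parameters.

    Training mode normalizes with batch statistics and accumulates running
    statistics; evaluation mode normalizes with the running statistics.  There
    are no learnable scale/shift parameters, so the pre-activation entering
    the nonlinearity always has mean 0 and variance 1 during training.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    @property
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool):
        c = x.shape[1]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(1, c, 1, 1)) * istd.reshape(1, c, 1, 1)
        return xhat, (xhat, istd, train)

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        xhat, istd, train = cache
        istd = istd.reshape(1, -1, 1, 1)
        if not train:
            return dy * istd
        mean_dy = dy.mean(axis=(0, 2, 3), keepdims=True)
        mean_dy_xhat = (dy * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (dy - mean_dy - xhat * mean_dy_xhat) * istd


def gain_relu(x: np.ndarray, gain: float) -> np.ndarray:
    """``y = G * max(0, x)`` — the gain G models neural excitability."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return gain * np.maximum(x, 0.0)


def gain_relu_forward(x: np.ndarray, gain: float):
    if gain <= 0:
        raise ValueError("gain must be positive")
    mask = x > 0
    return np.where(mask, x, 0.0) * gain, mask


def gain_relu_backward(dy: np.ndarray, mask: np.ndarray,
                       gain: float) -> np.ndarray:
    return np.where(mask, dy, 0.0) * gain


def maxpool2x2_forward(x: np.ndarray):
    """2x2/stride-2 max pooling; odd extents are zero-padded (inputs >= 0)."""
    n, c, h, w = x.shape
    ph, pw = h % 2, w % 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
    h2, w2 = x.shape[2] // 2, x.shape[3] // 2
    v = x.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(v).reshape(n, c, h2, w2, 4)
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    return y, (idx, (h, w))


def maxpool2x2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, (h, w) = cache
    n, c, h2, w2 = dy.shape
    dv = np.zeros((n, c, h2, w2, 4), dtype=dy.dtype)
    np.put_along_axis(dv, idx[..., None], dy[..., None], axis=-1)
    dx = dv.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    dx = dx.reshape(n, c, h2 * 2, w2 * 2)
    return dx[:, :, :h, :w]


def global_avgpool_forward(x: np.ndarray):
    return x.mean(axis=(2, 3)), x.shape[2:]


def global_avgpool_backward(dy: np.ndarray, hw) -> np.ndarray:
    h, w = hw
    return np.broadcast_to(dy[:, :, None, None] / (h * w),
                           dy.shape + (h, w)).copy()


class Linear:
    def __init__(self, nin: int, nout: int,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / nin)
        self.weight = Param(rng.uniform(-bound, bound,
                                        size=(nout, nin)).astype(dtype),
                            "linear.weight")
        self.bias = Param(np.zeros(nout, dtype=dtype), "linear.bias")

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray):
        return x @ self.weight.value.T + self.bias.value, x

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        x = cache
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-30)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p in self.params:
            p.m += (1.0 - self.beta1) * (p.grad - p.m)
            p.v += (1.0 - self.beta2) * (p.grad * p.grad - p.v)
            p.value -= self.lr * (p.m / b1c) / (np.sqrt(p.v / b2c) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [p.m.copy() for p in self.params],
                "v": [p.v.copy() for p in self.params]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for p, m, v in zip(self.params, state["m"], state["v"]):
            p.m[...] = m
            p.v[...] = v
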