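"""Minimal trainable neural-network layers on NumPy.

Just enough machinery for the patch classifier: valid/same 2-D convolution
(im2col), max/average pooling, dense layers, inverted dropout, residual
blocks, Adam, and softmax cross-entropy. Shapes follow the (N, C, H, W)
convention; all parameters are float32 and every source of randomness
(initialization, dropout masks) comes from generators the caller seeds, so
training runs are bit-reproducible on CPU.

Backward passes are exact gradients of the forward computation (verified by
finite differences in the test suite), with the usual subgradient choice at
ReLU kinks and max-pool ties.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its current gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param((rng.standard_normal((n_in, n_out)) * scale).astype(np.float32))
        self.b = Param(np.zeros(n_out, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix for a k x k window."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N, C, Ho, Wo, k, k
    n, c, ho, wo = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * k * k)


class Conv2D(Layer):
    """k x k convolution, stride 1, optional symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, pad: int = 0):
        self.c_in, self.c_out, self.k, self.pad = c_in, c_out, k, pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param((rng.standard_normal((c_out, c_in * k * k)) * scale).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self._xshape = x.shape
        n, _, h, w = x.shape
        self._ho, self._wo = h - self.k + 1, w - self.k + 1
        self._cols = _im2col(x, self.k)
        out = self._cols @ self.W.value.T + self.b.value
        return out.reshape(n, self._ho, self._wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n = grad.shape[0]
        gm = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.W.grad = gm.T @ self._cols
        self.b.grad = gm.sum(axis=0)
        # Input gradient: full correlation of grad with the 180deg-rotated
        # kernels, then strip the forward padding.
        k = self.k
        gpad = np.pad(grad, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        wrot = (
            self.W.value.reshape(self.c_out, self.c_in, k, k)[:, :, ::-1, ::-1]
            .transpose(1, 0, 2, 3)
            .reshape(self.c_in, self.c_out * k * k)
        )
        cols_g = _im2col(gpad, k)
        h, w = self._xshape[2], self._xshape[3]
        dx = (cols_g @ wrot.T).reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        if self.pad:
            p = self.pad
            dx = dx[:, :, p:-p, p:-p]
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        self._xw = xc.reshape(n, c, h2, 2, w2, 2)
        out = self._xw.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, grad):
        mask = self._xw == self._out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gw = mask * (grad[:, :, :, None, :, None] / counts)
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = gw.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class AvgPool(Layer):
    """k x k average pooling, stride k; trailing remainder rows/cols dropped."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        k = self.k
        hk, wk = h // k, w // k
        xc = x[:, :, : k * hk, : k * wk]
        return xc.reshape(n, c, hk, k, wk, k).mean(axis=(3, 5))

    def backward(self, grad):
        k = self.k
        n, c, h, w = self._in_shape
        hk, wk = h // k, w // k
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, : k * hk, : k * wk] = np.repeat(
            np.repeat(grad, k, axis=2), k, axis=3
        ) / (k * k)
        return dx


class Residual(Layer):
    """Identity-shortcut block: x + conv(relu(conv(x))), channels preserved."""

    def __init__(self, channels: int, rng: np.random.Generator, k: int = 3):
        pad = k // 2
        self.conv1 = Conv2D(channels, channels, k, rng, pad=pad)
        self.relu = ReLU()
        self.conv2 = Conv2D(channels, channels, k, rng, pad=pad)

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train=False, rng=None):
        return x + self.conv2.forward(self.relu.forward(self.conv1.forward(x)))

    def backward(self, grad):
        return grad + self.conv1.backward(self.relu.backward(self.conv2.backward(grad)))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with bias correction; the learning rate may be lowered mid-run
    (plateau scheduling) by assigning :attr:`lr`."""

    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over the batch plus d(loss)/d(logits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)
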