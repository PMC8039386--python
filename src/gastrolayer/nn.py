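"""Minimal NumPy neural-network layers with hand-written backprop.

Just enough machinery for the compact encoder-decoder used by wall
detection: 3x3 same-padding convolutions (im2col + matmul), ReLU, 2x2
max pooling, 2x2 stride-2 transposed convolution, channel
concatenation, 1x1 convolution and pixel-wise softmax cross-entropy,
trained with Adam.  Tensors are (N, C, H, W) float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.w = _he_init(rng, (c_in * 9, c_out), c_in * 9)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    @staticmethod
    def _im2col(x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * 9)

    def forward(self, x):
        self._shape = x.shape
        self._cols = self._im2col(x)
        n, c, h, w = x.shape
        out = self._cols @ self.w + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, h, w = self._shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n, h * w, self.c_out)
        self.grads[0][...] = np.einsum("npk,npo->ko", self._cols, dflat, optimize=True)
        self.grads[1][...] = dflat.sum(axis=(0, 1))
        self._cols = None
        # dx: correlate dout with the spatially flipped, channel-transposed kernel
        w4 = self.w.reshape(self.c_in, 3, 3, self.c_out)
        w_back = w4[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.c_out * 9, self.c_in)
        cols = self._im2col(dout)
        dx = cols @ w_back
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        xr = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(n, c, h, w)


class Deconv2x2(Layer):
    """2x2 stride-2 transposed convolution (each pixel -> 2x2 block)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.w = _he_init(rng, (c_in, c_out, 2, 2), c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        n, c, h, w = x.shape
        out = np.einsum("nchw,cokl->nohkwl", x, self.w, optimize=True)
        out = out.reshape(n, self.c_out, 2 * h, 2 * w)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        n, _, h2, w2 = dout.shape
        h, w = h2 // 2, w2 // 2
        d6 = dout.reshape(n, self.c_out, h, 2, w, 2)
        self.grads[0][...] = np.einsum("nchw,nohkwl->cokl", self._x, d6, optimize=True)
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nohkwl,cokl->nchw", d6, self.w, optimize=True)
        self._x = None
        return dx


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.w = _he_init(rng, (c_in, c_out), c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        out = np.einsum("nchw,co->nohw", x, self.w, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        self.grads[0][...] = np.einsum("nchw,nohw->co", self._x, dout, optimize=True)
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nohw,co->nchw", dout, self.w, optimize=True)
        self._x = None
        return dx


def softmax(logits):
    """Pixel-wise softmax over the channel axis of (N, C, H, W) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, target):
    """Mean pixel-wise cross-entropy and its gradient w.r.t. logits.

    ``target`` is an (N, H, W) integer class map.
    """
    p = softmax(logits)
    n, _, h, w = logits.shape
    picked = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    one = np.zeros_like(p)
    np.put_along_axis(one, target[:, None], 1.0, axis=1)
    grad = (p - one) / (n * h * w)
    return loss, grad.astype(np.float32)


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m[...] = self.b1 * m + (1 - self.b1) * g
                v[...] = self.b2 * v + (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
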