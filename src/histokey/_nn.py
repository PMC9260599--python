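"""Minimal convolutional network primitives (numpy, float32).

Internal building blocks for the patch autoencoder: stride-1/2 3x3
convolutions via im2col, nearest-neighbour 2x upsampling, ReLU/sigmoid,
and an Adam optimizer.  Layers keep persistent scratch buffers keyed by
input shape, so steady-state training performs no large allocations.
Everything is deterministic given the ``numpy.random.Generator`` used for
initialization and shuffling.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class _Buffered:
    """Mixin: named scratch arrays reused across calls of equal shape."""

    def _buf(self, name: str, shape, dtype=DTYPE) -> np.ndarray:
        bufs = getattr(self, "_bufs", None)
        if bufs is None:
            bufs = self._bufs = {}
        arr = bufs.get(name)
        if arr is None or arr.shape != tuple(shape) or arr.dtype != dtype:
            arr = np.empty(shape, dtype=dtype)
            bufs[name] = arr
        return arr


class Conv2d(_Buffered):
    """3x3 convolution, stride 1 or 2, padding 1."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator,
                 gain: str = "relu"):
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.k, self.pad = 3, 1
        fan_in = in_ch * self.k * self.k
        scale = np.sqrt(2.0 / fan_in) if gain == "relu" else np.sqrt(1.0 / fan_in)
        self.w = rng.normal(0.0, scale, size=(out_ch, fan_in)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def _im2col(self, x: np.ndarray):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = self._buf("xp", (n, c, h + 2 * p, w + 2 * p))
        xp.fill(0.0)
        xp[:, :, p : p + h, p : p + w] = x
        cols = self._buf("cols", (n, c, k, k, ho, wo))
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
        return cols.reshape(n, c * k * k, ho * wo), ho, wo

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n = x.shape[0]
        cols, ho, wo = self._im2col(x)
        out = self._buf("out", (n, self.out_ch, ho * wo))
        np.matmul(self.w, cols, out=out)
        out += self.b[None, :, None]
        if train:
            self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, self.out_ch, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        self._cache = None
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        d = dout.reshape(n, self.out_ch, ho * wo)
        gw_n = self._buf("gw_n", (n, self.out_ch, self.w.shape[1]))
        np.matmul(d, cols.transpose(0, 2, 1), out=gw_n)
        np.sum(gw_n, axis=0, out=self.gw)
        self.gb[...] = d.sum(axis=(0, 2))
        dcols = self._buf("dcols", (n, self.w.shape[1], ho * wo))
        np.matmul(self.w.T, d, out=dcols)
        # scatter-add back to the padded input (col2im)
        dxp = self._buf("dxp", (n, c, h + 2 * p, w + 2 * p))
        dxp.fill(0.0)
        dc = dcols.reshape(n, c, k, k, ho, wo)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dc[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class Dense(_Buffered):
    """Fully connected layer over (N, d_in) activations."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 gain: str = "linear"):
        scale = np.sqrt(2.0 / d_in) if gain == "relu" else np.sqrt(1.0 / d_in)
        self.w = rng.normal(0.0, scale, size=(d_out, d_in)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=False):
        out = self._buf("out", (x.shape[0], self.w.shape[0]))
        np.matmul(x, self.w.T, out=out)
        out += self.b
        if train:
            xc = self._buf("xc", x.shape)
            xc[:] = x
            self._x = xc
        return out

    def backward(self, dout):
        self.gw[...] = dout.T @ self._x
        self.gb[...] = dout.sum(axis=0)
        self._x = None
        dx = self._buf("dx", (dout.shape[0], self.w.shape[1]))
        np.matmul(dout, self.w, out=dx)
        return dx


class Flatten:
    """(N, C, H, W) <-> (N, C*H*W)."""

    def params(self):
        return []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape:
    """(N, D) -> (N, *shape)."""

    def __init__(self, shape):
        self.shape = tuple(shape)

    def params(self):
        return []

    def forward(self, x, train=False):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(dout.shape[0], -1)


class ReLU(_Buffered):
    def params(self):
        return []

    def forward(self, x, train=False):
        if train:
            mask = self._buf("mask", x.shape, dtype=bool)
            np.greater(x, 0, out=mask)
            self._mask = mask
            return np.multiply(x, mask, out=x)
        return np.maximum(x, 0, out=x)

    def backward(self, dout):
        dout *= self._mask
        return dout


class Sigmoid(_Buffered):
    def params(self):
        return []

    def forward(self, x, train=False):
        y = self._buf("y", x.shape)
        np.multiply(x, -1.0, out=y)
        np.exp(y, out=y)
        y += 1.0
        np.reciprocal(y, out=y)
        self._y = y if train else None
        return y

    def backward(self, dout):
        # d/dx sigmoid = y * (1 - y)
        g = self._buf("g", dout.shape)
        np.subtract(1.0, self._y, out=g)
        g *= self._y
        dout = np.multiply(dout, g, out=g)
        return dout


class Upsample2x(_Buffered):
    """Nearest-neighbour 2x spatial upsampling."""

    def params(self):
        return []

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        out = self._buf("out", (n, c, 2 * h, 2 * w))
        for dy in (0, 1):
            for dx in (0, 1):
                out[:, :, dy::2, dx::2] = x
        return out

    def backward(self, dout):
        n, c, h, w = dout.shape
        dx = self._buf("dx", (n, c, h // 2, w // 2))
        dx[:] = dout[:, :, 0::2, 0::2]
        for dy, dxo in ((0, 1), (1, 0), (1, 1)):
            dx += dout[:, :, dy::2, dxo::2]
        return dx


def forward_chain(layers, x, train=False):
    for layer in layers:
        x = layer.forward(x, train=train)
    return x


def backward_chain(layers, dout):
    for layer in reversed(layers):
        dout = layer.backward(dout)
    return dout


class Adam:
    """Adam optimizer over the parameters of a list of layers."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = [pg for layer in layers for pg in layer.params()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
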