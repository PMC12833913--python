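"""Minimal numpy neural-network layers with reverse-mode gradients.

Implements exactly the layer set needed for a single-channel
super-resolution GAN: 2-D convolution (arbitrary kernel/stride, "same"
padding), batch normalization, ReLU / leaky-ReLU / tanh / sigmoid,
sub-pixel (pixel-shuffle) upsampling, 2x2 max pooling, global average
pooling, and a fully connected layer, plus an Adam optimizer with
step-wise learning-rate decay.

Every layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward``; parameter gradients
accumulate in ``layer.grads``.  All floating arithmetic is float64 so
that seeded runs are bit-reproducible on one thread.

Tensors are NCHW: (batch, channels, rows, cols).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm2d", "ReLU", "LeakyReLU", "Tanh",
    "Sigmoid", "PixelShuffle", "MaxPool2d", "GlobalAvgPool", "Linear",
    "Sequential", "ResidualBlock", "Adam",
]


class Layer:
    """Base class: parameter-free identity."""

    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """2-D convolution with "same" zero padding (odd kernels) and stride.

    The spatial loops run over the kernel offsets only (k*k iterations),
    with the heavy contraction done by einsum over batch x channels, so
    cost is a dense matmul per offset.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernels only")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        fan_in = in_ch * kernel * kernel
        self.w = _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.dw, self.db]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.k // 2
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.broadcast_to(self.b[None, :, None, None], (n, self.out_ch, ho, wo)).copy()
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                out += np.einsum("nchw,oc->nohw", patch, self.w[:, :, i, j],
                                 optimize=True)
        self._cache = (xp, x.shape, (ho, wo))
        return out

    def backward(self, dout):
        xp, xshape, (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.k // 2
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                self.dw[:, :, i, j] += np.einsum("nohw,nchw->oc", dout, patch,
                                                 optimize=True)
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += np.einsum(
                    "nohw,oc->nchw", dout, self.w[:, :, i, j], optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        n, c, h, w = xshape
        return dxp[:, :, p:p + h, p:p + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.dgamma = np.zeros(ch)
        self.dbeta = np.zeros(ch)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.run_mean = np.zeros(ch)
        self.run_var = np.ones(ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class PixelShuffle(Layer):
    """Sub-pixel upsampling: (N, C*r^2, H, W) -> (N, C, H*r, W*r)."""

    def __init__(self, r: int = 2):
        super().__init__()
        self.r = r

    def forward(self, x, train=True):
        n, crr, h, w = x.shape
        r = self.r
        c = crr // (r * r)
        self._shape = x.shape
        y = x.reshape(n, c, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
        return y.reshape(n, c, h * r, w * r)

    def backward(self, dout):
        n, crr, h, w = self._shape
        r = self.r
        c = crr // (r * r)
        d = dout.reshape(n, c, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
        return d.reshape(self._shape)


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling (even spatial dims required)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        self._shape = x.shape
        return y

    def backward(self, dout):
        n, c, h, w = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).copy()


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.dw, self.db]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.w.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)
        for lyr in self.layers:
            self.params.extend(lyr.params)
            self.grads.extend(lyr.grads)

    def forward(self, x, train=True):
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x

    def backward(self, dout):
        for lyr in reversed(self.layers):
            dout = lyr.backward(dout)
        return dout

    def zero_grads(self):
        for lyr in self.layers:
            lyr.zero_grads()


class ResidualBlock(Layer):
    """conv3-BN-ReLU-conv3-BN with an identity skip."""

    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.body = Sequential(
            Conv2d(ch, ch, 3, rng=rng), BatchNorm2d(ch), ReLU(),
            Conv2d(ch, ch, 3, rng=rng), BatchNorm2d(ch),
        )
        self.params = self.body.params
        self.grads = self.body.grads

    def forward(self, x, train=True):
        return x + self.body.forward(x, train=train)

    def backward(self, dout):
        return dout + self.body.backward(dout)

    def zero_grads(self):
        self.body.zero_grads()


def iter_modules(root: Layer):
    """Depth-first walk over a layer tree (containers included)."""
    yield root
    for attr in ("layers", "body", "head", "res", "post", "post_act", "up",
                 "tail", "net"):
        child = getattr(root, attr, None)
        if isinstance(child, Layer):
            yield from iter_modules(child)
        elif isinstance(child, (list, tuple)):
            for item in child:
                if isinstance(item, Layer):
                    yield from iter_modules(item)


class Adam:
    """Adam with optional step-wise learning-rate halving.

    ``decay_interval`` is in optimizer steps; after every interval the
    effective rate is multiplied by ``decay_factor``.
    """

    def __init__(self, net: Layer, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, decay_interval: int = 1000,
                 decay_factor: float = 0.5):
        self.net = net
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.decay_interval = decay_interval
        self.decay_factor = decay_factor
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.params]
        self.v = [np.zeros_like(p) for p in net.params]

    @property
    def lr(self) -> float:
        return self.lr0 * self.decay_factor ** (self.t // self.decay_interval)

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        for p, g, m, v in zip(self.net.params, self.net.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
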