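"""Trainable layers with explicit forward/backward passes.

Minimal NumPy training engine used by the network builders: every layer
caches what its backward pass needs during ``forward`` and accumulates
parameter gradients during ``backward``. Tensors are batched ``(N, C, H, W)``
float32 arrays. The math mirrors the pure functional contracts in
:mod:`lwseg.blocks` (which operate on single ``(H, W, C)`` maps); the two
implementations are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

from .blocks import upsample_matrix


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class; subclasses implement forward/backward and list params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class DepthwiseConv3x3(Layer):
    """Per-channel 3x3 convolution with dilation and same-size zero padding."""

    def __init__(self, channels: int, dilation: int, rng: np.random.Generator) -> None:
        self.channels = channels
        self.dilation = dilation
        self.w = Param(he_init(rng, (channels, 3, 3), 9), f"dw{dilation}.w")

    def params(self) -> list[Param]:
        return [self.w]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = self.dilation
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (d, d), (d, d)))
        self._xp, self._shape = xp, x.shape
        out = np.zeros_like(x)
        wv = self.w.value
        for i in range(3):
            for j in range(3):
                out += wv[None, :, i, j, None, None] * xp[:, :, i * d:i * d + h, j * d:j * d + w]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        d = self.dilation
        n, c, h, w = self._shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        wv = self.w.value
        for i in range(3):
            for j in range(3):
                patch = xp[:, :, i * d:i * d + h, j * d:j * d + w]
                self.w.grad[:, i, j] += np.einsum("nchw,nchw->c", g, patch)
                dxp[:, :, i * d:i * d + h, j * d:j * d + w] += wv[None, :, i, j, None, None] * g
        self._xp = None
        return dxp[:, :, d:d + h, d:d + w]


class PointwiseConv(Layer):
    """1x1 convolution (channel mixing) with optional bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(he_init(rng, (c_out, c_in), c_in), "pw.w")
        self.b = Param(np.zeros(c_out, dtype=np.float32), "pw.b") if bias else None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        flat = x.transpose(1, 0, 2, 3).reshape(c, -1)          # (Cin, N*H*W)
        out = (self.w.value @ flat).reshape(self.c_out, n, h, w).transpose(1, 0, 2, 3)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x.shape
        gf = g.transpose(1, 0, 2, 3).reshape(self.c_out, -1)
        xf = self._x.transpose(1, 0, 2, 3).reshape(c, -1)
        self.w.grad += gf @ xf.T
        if self.b is not None:
            self.b.grad += gf.sum(axis=1)
        dx = (self.w.value.T @ gf).reshape(c, n, h, w).transpose(1, 0, 2, 3)
        self._x = None
        return dx


class BatchNorm(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += np.einsum("nchw,nchw->c", g, xhat)
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gi = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        if not self._train:
            return gi * g
        m = g.shape[0] * g.shape[2] * g.shape[3]
        gm = g.mean(axis=(0, 2, 3))[None, :, None, None]
        gxm = np.einsum("nchw,nchw->c", g, xhat)[None, :, None, None] / m
        dx = gi * (g - gm - xhat * gxm)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, g, 0.0)
        self._mask = None
        return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clamp so float32 exp never overflows and the gate stays inside (0, 1)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class LHA(Layer):
    """Lightweight hybrid attention: channel gate then spatial gate.

    Channel branch: global max + mean per channel, shared 1x3 1-D convolution
    along the channel axis (zero padded), sigmoid, multiplicative gate.
    Spatial branch (on the channel-gated map): channel-wise max + mean maps
    added, 7x7 same-padded convolution, sigmoid, multiplicative gate.
    """

    def __init__(self, rng: np.random.Generator) -> None:
        self.ck = Param(he_init(rng, (3,), 3), "lha.ck")
        self.cb = Param(np.zeros(1, dtype=np.float32), "lha.cb")
        self.sk = Param(he_init(rng, (7, 7), 49), "lha.sk")
        self.sb = Param(np.zeros(1, dtype=np.float32), "lha.sb")

    def params(self) -> list[Param]:
        return [self.ck, self.cb, self.sk, self.sb]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        # --- channel gate ---
        flat = x.reshape(n, c, -1)
        self._argmax_hw = flat.argmax(axis=2)                 # (N, C)
        mx = np.take_along_axis(flat, self._argmax_hw[:, :, None], axis=2)[:, :, 0]
        av = flat.mean(axis=2)
        s = np.pad(mx + av, ((0, 0), (1, 1)))                 # (N, C+2)
        k = self.ck.value
        z = k[0] * s[:, :-2] + k[1] * s[:, 1:-1] + k[2] * s[:, 2:] + self.cb.value[0]
        cw = _sigmoid(z)                                      # (N, C)
        x1 = x * cw[:, :, None, None]
        # --- spatial gate ---
        self._argmax_c = x1.argmax(axis=1)                    # (N, H, W)
        smax = np.take_along_axis(x1, self._argmax_c[:, None], axis=1)[:, 0]
        smean = x1.mean(axis=1)
        sp = np.pad(smax + smean, ((0, 0), (3, 3), (3, 3)))
        z2 = np.full((n, h, w), self.sb.value[0], dtype=x.dtype)
        skv = self.sk.value
        for i in range(7):
            for j in range(7):
                z2 += skv[i, j] * sp[:, i:i + h, j:j + w]
        sw = _sigmoid(z2)                                     # (N, H, W)
        self._cache = (x, cw, x1, sp, sw, s)
        return x1 * sw[:, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, cw, x1, sp, sw, s = self._cache
        n, c, h, w = x.shape
        # through spatial gate
        dx1 = g * sw[:, None]
        dsw = np.einsum("nchw,nchw->nhw", g, x1)
        dz2 = dsw * sw * (1.0 - sw)
        dsp = np.zeros_like(sp)
        skv = self.sk.value
        for i in range(7):
            for j in range(7):
                self.sk.grad[i, j] += np.einsum("nhw,nhw->", dz2, sp[:, i:i + h, j:j + w])
                dsp[:, i:i + h, j:j + w] += skv[i, j] * dz2
        self.sb.grad[0] += dz2.sum()
        ds = dsp[:, 3:3 + h, 3:3 + w]                         # grad wrt smax + smean
        # mean path
        dx1 += ds[:, None] / c
        # max path (route to argmax channel)
        ni, hi, wi = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
        np.add.at(dx1, (ni, self._argmax_c, hi, wi), ds)
        # through channel gate
        dx = dx1 * cw[:, :, None, None]
        dcw = np.einsum("nchw,nchw->nc", dx1, x)
        dz = dcw * cw * (1.0 - cw)
        k = self.ck.value
        self.ck.grad[0] += np.einsum("nc,nc->", dz, s[:, :-2])
        self.ck.grad[1] += np.einsum("nc,nc->", dz, s[:, 1:-1])
        self.ck.grad[2] += np.einsum("nc,nc->", dz, s[:, 2:])
        self.cb.grad[0] += dz.sum()
        # transpose of z[c] = sum_t k[t] * s_padded[c + t]: ds[j] = sum_t k[t] * dz[j - t]
        dsum = k[0] * np.pad(dz, ((0, 0), (0, 2))) + \
            k[1] * np.pad(dz, ((0, 0), (1, 1))) + \
            k[2] * np.pad(dz, ((0, 0), (2, 0)))
        dsum = dsum[:, 1:-1]                                  # (N, C), grad wrt mx + av
        # mean path
        dx += dsum[:, :, None, None] / (h * w)
        # max path (route to argmax pixel)
        dxf = dx.reshape(n, c, -1)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(dxf, (ni, ci, self._argmax_hw), dsum)
        self._cache = None
        return dxf.reshape(n, c, h, w)


class SSPDC(Layer):
    """Depthwise pyramid (dilations 1/2/3) + pointwise fusion, BN, ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bn_relu: bool = True) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.branches = [DepthwiseConv3x3(c_in, d, rng) for d in (1, 2, 3)]
        self.pw = PointwiseConv(3 * c_in, c_out, rng)
        self.bn = BatchNorm(c_out) if bn_relu else None
        self.relu = ReLU() if bn_relu else None

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.branches:
            ps.extend(b.params())
        ps.extend(self.pw.params())
        if self.bn is not None:
            ps.extend(self.bn.params())
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {x.shape[1]}")
        cat = np.concatenate([b.forward(x, train) for b in self.branches], axis=1)
        out = self.pw.forward(cat, train)
        if self.bn is not None:
            out = self.relu.forward(self.bn.forward(out, train), train)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.bn is not None:
            g = self.bn.backward(self.relu.backward(g))
        dcat = self.pw.backward(g)
        c = self.c_in
        dx = self.branches[0].backward(dcat[:, :c])
        dx += self.branches[1].backward(dcat[:, c:2 * c])
        dx += self.branches[2].backward(dcat[:, 2 * c:])
        return dx


class MaxPool2x2(Layer):
    """2x2 stride-2 max pooling; stores window-flat argmax (row-major ties).

    Besides the per-channel indices it records a channel-shared window index
    (the argmax of the channel-mean activation) so a decoder whose width
    differs from the encoder's can still unpool sparsely.
    """

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, h // 2, w // 2, 4)
        self.idx = flat.argmax(axis=4)
        self.shared_idx = flat.mean(axis=1).argmax(axis=3)    # (N, H/2, W/2)
        self._shape = x.shape
        return np.take_along_axis(flat, self.idx[..., None], axis=4)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        df = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(df, self.idx[..., None], g[..., None], axis=4)
        return df.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class MaxUnpool2x2(Layer):
    """Inverse of :class:`MaxPool2x2` given that pool's stored indices.

    Uses the per-channel argmax indices when the incoming width matches the
    encoder's; otherwise the channel-shared window index is broadcast over
    all channels.
    """

    def __init__(self, pool: MaxPool2x2) -> None:
        self.pool = pool

    def _indices(self, c: int) -> np.ndarray:
        if c == self.pool.idx.shape[1]:
            return self.pool.idx
        n, h2, w2 = self.pool.shared_idx.shape
        return np.broadcast_to(self.pool.shared_idx[:, None], (n, c, h2, w2))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h2, w2 = x.shape
        df = np.zeros((n, c, h2, w2, 4), dtype=x.dtype)
        np.put_along_axis(df, self._indices(c)[..., None], x[..., None], axis=4)
        return df.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = g.shape
        win = g.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, h // 2, w // 2, 4)
        return np.take_along_axis(flat, self._indices(c)[..., None], axis=4)[..., 0]


class BilinearUp2x(Layer):
    """Parameter-free bilinear 2x upsampling (half-pixel-center convention)."""

    _cache_mats: dict[int, np.ndarray] = {}

    @classmethod
    def _mat(cls, n: int) -> np.ndarray:
        if n not in cls._cache_mats:
            cls._cache_mats[n] = upsample_matrix(n).astype(np.float32)
        return cls._cache_mats[n]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        ah, aw = self._mat(h), self._mat(w)
        t = np.matmul(ah, x.reshape(n * c, h, w))
        return np.matmul(t, aw.T).reshape(n, c, 2 * h, 2 * w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        ah, aw = self._mat(h), self._mat(w)
        t = np.matmul(ah.T, g.reshape(n * c, 2 * h, 2 * w))
        return np.matmul(t, aw).reshape(n, c, h, w)


def softmax_channel(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
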