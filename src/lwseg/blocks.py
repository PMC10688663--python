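"""Pure computational blocks of the lightweight segmentation networks.

Everything in this module is a deterministic function of an ``(H, W, C)``
feature map and an explicit parameter container: the lightweight hybrid
attention (LHA) module, the separable spatial pyramid dilated convolution
(SSPDC), max pooling with stored argmax indices and its inverse unpooling,
and parameter-free bilinear 2x upsampling.

Conventions
-----------
* Feature maps are ``float`` arrays of shape ``(H, W, C)`` with all values
  finite; attention weights are sigmoid outputs, hence strictly in (0, 1).
* The SSPDC pyramid uses 3x3 depthwise kernels at dilation rates 1, 2 and 3,
  giving effective receptive fields of 3, 5 and 7 pixels; the three branch
  outputs are concatenated channel-wise and fused by a pointwise (1x1)
  convolution.
* Max pooling is 2x2, stride 2; ties break to the first occurrence in
  row-major order within the window.
* Bilinear upsampling uses the half-pixel-center convention (output sample
  ``j`` reads input coordinate ``(j + 0.5) / 2 - 0.5``, clamped at the edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LHAParams",
    "SSPDCParams",
    "channel_attention",
    "spatial_attention",
    "apply_lha",
    "sspdc_forward",
    "maxpool_with_indices",
    "max_unpool",
    "bilinear_upsample2x",
    "upsample_matrix",
]


def _validate_fm(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=np.float64)
    if fm.ndim != 3:
        raise ValueError(f"feature map must be (H, W, C), got shape {fm.shape}")
    if min(fm.shape) < 1:
        raise ValueError(f"feature map dimensions must be >= 1, got {fm.shape}")
    if not np.all(np.isfinite(fm)):
        raise ValueError("feature map contains non-finite values")
    return fm


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clamped so the result is strictly inside (0, 1) even for extreme inputs
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700.0, 700.0)))


@dataclass
class LHAParams:
    """Weights of one LHA module.

    ``channel_kernel`` is the 1x3 weight vector of the 1-D convolution run
    along the channel axis (shared by the max- and average-pooled vectors,
    which is equivalent to convolving their sum); ``spatial_kernel`` is the
    7x7 kernel applied to the sum of the channel-wise max and mean maps.
    """

    channel_kernel: np.ndarray = field(default_factory=lambda: np.zeros(3))
    channel_bias: float = 0.0
    spatial_kernel: np.ndarray = field(default_factory=lambda: np.zeros((7, 7)))
    spatial_bias: float = 0.0

    def __post_init__(self) -> None:
        self.channel_kernel = np.asarray(self.channel_kernel, dtype=np.float64)
        self.spatial_kernel = np.asarray(self.spatial_kernel, dtype=np.float64)
        if self.channel_kernel.shape != (3,):
            raise ValueError("channel kernel must have length 3")
        if self.spatial_kernel.shape != (7, 7):
            raise ValueError("spatial kernel must be 7x7")


@dataclass
class SSPDCParams:
    """Weights of one SSPDC block mapping ``c_in`` to ``c_out`` channels.

    ``depthwise`` holds three kernels of shape ``(c_in, 3, 3)`` used at
    dilation rates 1, 2 and 3; ``pointwise`` has shape ``(c_out, 3 * c_in)``
    and consumes the channel-concatenated branch outputs (branch-major
    layout: branch 0 channels first).
    """

    depthwise: np.ndarray
    pointwise: np.ndarray
    bias: np.ndarray | None = None

    dilations = (1, 2, 3)

    def __post_init__(self) -> None:
        self.depthwise = np.asarray(self.depthwise, dtype=np.float64)
        self.pointwise = np.asarray(self.pointwise, dtype=np.float64)
        if self.depthwise.ndim != 4 or self.depthwise.shape[0] != 3 \
                or self.depthwise.shape[2:] != (3, 3):
            raise ValueError("depthwise kernels must have shape (3, c_in, 3, 3)")
        c_in = self.depthwise.shape[1]
        if self.pointwise.ndim != 2 or self.pointwise.shape[1] != 3 * c_in:
            raise ValueError(
                f"pointwise kernel must be (c_out, {3 * c_in}) for c_in={c_in}, "
                f"got {self.pointwise.shape}")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.pointwise.shape[0],):
                raise ValueError("bias must have one entry per output channel")

    @property
    def c_in(self) -> int:
        return self.depthwise.shape[1]

    @property
    def c_out(self) -> int:
        return self.pointwise.shape[0]

    @classmethod
    def identity(cls, c: int) -> "SSPDCParams":
        """Parameters that make the block an exact identity map.

        Each depthwise branch is a centred delta kernel and the pointwise
        convolution averages the three identical copies of each channel.
        """
        dw = np.zeros((3, c, 3, 3))
        dw[:, :, 1, 1] = 1.0
        pw = np.zeros((c, 3 * c))
        for ch in range(c):
            pw[ch, [ch, c + ch, 2 * c + ch]] = 1.0 / 3.0
        return cls(depthwise=dw, pointwise=pw, bias=np.zeros(c))


def _conv1d_channels(v: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """1-D convolution of a length-C vector with a length-3 kernel, zero padded."""
    vp = np.pad(v, 1)
    return kernel[0] * vp[:-2] + kernel[1] * vp[1:-1] + kernel[2] * vp[2:]


def channel_attention(fm: np.ndarray, params: LHAParams) -> np.ndarray:
    """Per-channel attention weights in (0, 1).

    Global (1x1-output) max and average pooling reduce each band to a scalar;
    the two length-C vectors are passed through a shared 1x3 1-D convolution
    (zero padding at the channel-axis ends), summed, and squashed by a
    sigmoid.
    """
    fm = _validate_fm(fm)
    mx = fm.max(axis=(0, 1))
    av = fm.mean(axis=(0, 1))
    # conv1d(mx, k) + conv1d(av, k) == conv1d(mx + av, k) by linearity
    z = _conv1d_channels(mx + av, params.channel_kernel) + params.channel_bias
    return _sigmoid(z)


def _conv2d_same(x: np.ndarray, kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Single-channel 2-D convolution with same-size zero padding."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((ph, ph), (pw, pw)))
    h, w = x.shape
    out = np.full((h, w), bias, dtype=np.float64)
    for i in range(kh):
        for j in range(kw):
            out += kernel[i, j] * xp[i:i + h, j:j + w]
    return out


def spatial_attention(fm: np.ndarray, params: LHAParams) -> np.ndarray:
    """Per-pixel attention weights in (0, 1).

    The channel-wise max map and mean map are added (not concatenated) and
    convolved with a single 7x7 kernel under same-size zero padding before
    the sigmoid.
    """
    fm = _validate_fm(fm)
    s = fm.max(axis=2) + fm.mean(axis=2)
    z = _conv2d_same(s, params.spatial_kernel, params.spatial_bias)
    return _sigmoid(z)


def apply_lha(fm: np.ndarray, params: LHAParams) -> np.ndarray:
    """Sequential multiplicative channel-then-spatial attention gating.

    The channel weights rescale the input; spatial attention is computed on
    the channel-gated map and applied on top. Both gates are in (0, 1), so
    the module never increases the magnitude of any activation.
    """
    fm = _validate_fm(fm)
    gated = fm * channel_attention(fm, params)[None, None, :]
    return gated * spatial_attention(gated, params)[:, :, None]


def _depthwise_same(fm: np.ndarray, kernels: np.ndarray, dilation: int) -> np.ndarray:
    """Depthwise 3x3 convolution with dilation and same-size zero padding.

    ``kernels`` has shape ``(C, 3, 3)``; ``fm`` is ``(H, W, C)``.
    """
    h, w, _ = fm.shape
    d = dilation
    xp = np.pad(fm, ((d, d), (d, d), (0, 0)))
    out = np.zeros_like(fm)
    for i in range(3):
        for j in range(3):
            out += kernels[:, i, j][None, None, :] * xp[i * d:i * d + h, j * d:j * d + w, :]
    return out


def sspdc_forward(fm: np.ndarray, params: SSPDCParams) -> np.ndarray:
    """Separable spatial pyramid dilated convolution.

    Three depthwise 3x3 branches at dilation rates 1, 2, 3 (effective
    receptive fields 3, 5, 7) run on the input; their outputs are
    concatenated along the channel axis and fused to ``c_out`` channels by a
    pointwise convolution. Spatial shape is preserved.
    """
    fm = _validate_fm(fm)
    if fm.shape[2] != params.c_in:
        raise ValueError(
            f"channel mismatch: feature map has {fm.shape[2]} channels, "
            f"parameters expect {params.c_in}")
    branches = [
        _depthwise_same(fm, params.depthwise[b], d)
        for b, d in enumerate(params.dilations)
    ]
    stacked = np.concatenate(branches, axis=2)            # (H, W, 3*c_in)
    out = stacked @ params.pointwise.T                    # (H, W, c_out)
    if params.bias is not None:
        out = out + params.bias
    return out


def maxpool_with_indices(fm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 stride-2 max pooling returning pooled values and argmax positions.

    Returns ``(pooled, idx)`` where ``pooled`` is ``(H/2, W/2, C)`` and
    ``idx`` is ``(H/2, W/2, C, 2)`` holding the (row, col) of each window
    maximum in pre-pool coordinates. Ties break to the first occurrence in
    row-major order. Odd spatial dimensions are rejected.
    """
    fm = _validate_fm(fm)
    h, w, c = fm.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    win = fm.reshape(h // 2, 2, w // 2, 2, c).transpose(0, 2, 4, 1, 3)
    flat = win.reshape(h // 2, w // 2, c, 4)
    k = flat.argmax(axis=3)                               # first max, row-major
    pooled = np.take_along_axis(flat, k[..., None], axis=3)[..., 0]
    rows = 2 * np.arange(h // 2)[:, None, None] + k // 2
    cols = 2 * np.arange(w // 2)[None, :, None] + k % 2
    return pooled, np.stack([rows, cols], axis=3)


def max_unpool(fm: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Place pooled values back at their argmax positions, zeros elsewhere."""
    fm = _validate_fm(fm)
    h2, w2, c = fm.shape
    idx = np.asarray(idx)
    if idx.shape != (h2, w2, c, 2):
        raise ValueError(f"index map shape {idx.shape} does not match {fm.shape}")
    rows, cols = idx[..., 0], idx[..., 1]
    base_r = 2 * np.arange(h2)[:, None, None]
    base_c = 2 * np.arange(w2)[None, :, None]
    if np.any((rows < base_r) | (rows > base_r + 1) | (cols < base_c) | (cols > base_c + 1)):
        raise ValueError("an index lies outside its 2x2 pooling window")
    out = np.zeros((2 * h2, 2 * w2, c), dtype=fm.dtype)
    ch = np.broadcast_to(np.arange(c)[None, None, :], rows.shape)
    out[rows, cols, ch] = fm
    return out


def upsample_matrix(n: int) -> np.ndarray:
    """Dense ``(2n, n)`` interpolation matrix for 1-D bilinear 2x upsampling.

    Half-pixel-center convention: output sample ``j`` reads source coordinate
    ``(j + 0.5) / 2 - 0.5``, clamped to ``[0, n - 1]``.
    """
    src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    src = np.clip(src, 0.0, n - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    frac = src - i0
    a = np.zeros((2 * n, n))
    a[np.arange(2 * n), i0] += 1.0 - frac
    a[np.arange(2 * n), i1] += frac
    return a


def bilinear_upsample2x(fm: np.ndarray) -> np.ndarray:
    """Parameter-free bilinear 2x upsampling to ``(2H, 2W, C)``."""
    fm = _validate_fm(fm)
    h, w, _ = fm.shape
    ah, aw = upsample_matrix(h), upsample_matrix(w)
    return np.einsum("ph,hwc,qw->pqc", ah, fm, aw, optimize=True)
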