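"""LW-Segnet and LW-Unet assembly plus analytic efficiency profiling.

Both networks are four-stage encoder--decoder CNNs over 5-band input built
from the blocks in :mod:`lwseg.layers`:

* every stage applies a lightweight hybrid attention (LHA) gate before its
  convolution stack, and every convolution is an SSPDC (depthwise dilation
  pyramid + pointwise fusion) followed by batch normalisation and ReLU;
* LW-Segnet uses (2, 1, 1, 5) convolutions per encoder stage and (5, 1, 1, 2)
  per decoder stage, 2x2 max pooling with stored argmax indices, and
  SegNet-style sparse unpooling in the decoder;
* LW-Unet uses 2 convolutions per stage, plain max pooling, parameter-free
  bilinear 2x upsampling and U-Net-style channel concatenation skips.

Each stage's convolution stack runs at that stage's coarser resolution and
the stage ends with its down-/up-sampling step, so the widest decoder stack
sits at 1/16 of the input resolution; the per-stage channel widths are
explicit configuration, with shipped defaults calibrated once against the
published complexity budgets (11.0 M parameters / 36.8 GFLOPs for LW-Segnet
and 10.6 M / 32.1 G for LW-Unet at 512x512x5 input).

The profiler (:func:`count_parameters`, :func:`count_flops`) is analytic: it
derives every layer's cost from the architecture specification without
building weight arrays, and is cross-checked against the built model's own
parameter tally. FLOP convention: one multiply-accumulate = 2 FLOPs, counted
per convolution as ``2 * Kh * Kw * Cin_per_group * Cout * Hout * Wout``;
batch norm, ReLU, pooling, unpooling, interpolation and softmax count 1 FLOP
per output element; the channel-attention 1-D convolution costs ``6 * C + C``
FLOPs independent of the spatial size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    LHA,
    BilinearUp2x,
    Layer,
    MaxPool2x2,
    MaxUnpool2x2,
    Param,
    PointwiseConv,
    SSPDC,
    softmax_channel,
)

SEGNET_ENCODER_CONVS = (2, 1, 1, 5)
SEGNET_DECODER_CONVS = (5, 1, 1, 2)
UNET_CONVS = (2, 2, 2, 2)

#: Calibrated per-stage channel widths (see module docstring). Frozen.
DEFAULT_WIDTHS = {
    "lw_segnet": {"encoder": (32, 64, 80, 216), "decoder": (880, 112, 72, 16)},
    "lw_unet": {"encoder": (16, 24, 80, 232), "decoder": (1680, 88, 64, 24)},
}

#: Narrow ladder for desk-scale (CPU) training experiments and smoke runs.
COMPACT_WIDTHS = {"encoder": (8, 16, 32, 48), "decoder": (64, 32, 16, 8)}


@dataclass(frozen=True)
class StageSpec:
    """One encoder or decoder stage: conv count, widths, skip wiring."""

    conv_count: int
    in_width: int
    out_width: int
    attention: bool = True
    skip_kind: str = "none"  # pool_indices | concat | none

    def __post_init__(self) -> None:
        if self.conv_count < 1 or self.in_width < 1 or self.out_width < 1:
            raise ValueError("conv_count and widths must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one network; models and profiles derive from it."""

    name: str
    input_channels: int = 5
    classes: int = 2
    input_size: int = 512
    encoder_widths: tuple[int, int, int, int] = ()
    decoder_widths: tuple[int, int, int, int] = ()

    def __post_init__(self) -> None:
        if self.name not in ("lw_segnet", "lw_unet"):
            raise ValueError(f"unknown architecture {self.name!r}")
        if self.input_size % 16:
            raise ValueError("input size must be divisible by 16 (four pooling stages)")
        for w in (self.encoder_widths, self.decoder_widths):
            if len(w) != 4 or any(x < 1 for x in w):
                raise ValueError("need 4 positive widths per path")

    @property
    def encoder_conv_counts(self) -> tuple[int, ...]:
        return SEGNET_ENCODER_CONVS if self.name == "lw_segnet" else UNET_CONVS

    @property
    def decoder_conv_counts(self) -> tuple[int, ...]:
        return SEGNET_DECODER_CONVS if self.name == "lw_segnet" else UNET_CONVS

    @property
    def encoder_stages(self) -> tuple[StageSpec, ...]:
        skip = "pool_indices" if self.name == "lw_segnet" else "concat"
        ins = (self.input_channels,) + self.encoder_widths[:3]
        return tuple(
            StageSpec(n, ci, co, attention=True, skip_kind=skip)
            for n, ci, co in zip(self.encoder_conv_counts, ins, self.encoder_widths))

    @property
    def decoder_stages(self) -> tuple[StageSpec, ...]:
        stages = []
        for k, (n, d) in enumerate(zip(self.decoder_conv_counts, self.decoder_widths)):
            ci = self._decoder_in_width(k)
            skip = "pool_indices" if self.name == "lw_segnet" else (
                "concat" if k > 0 else "none")
            stages.append(StageSpec(n, ci, d, attention=True, skip_kind=skip))
        return tuple(stages)

    def _decoder_in_width(self, k: int) -> int:
        e, d = self.encoder_widths, self.decoder_widths
        if k == 0:
            return e[3]
        prev = d[k - 1]
        if self.name == "lw_unet":
            return prev + e[4 - k]  # concat with the encoder stage (5-k) skip
        return prev

    @property
    def head_in_width(self) -> int:
        if self.name == "lw_unet":
            return self.decoder_widths[3] + self.encoder_widths[0]
        return self.decoder_widths[3]


def default_spec(name: str, input_size: int = 512, input_channels: int = 5,
                 widths: dict | None = None) -> ArchitectureSpec:
    """Spec with the calibrated default width ladder for ``name``."""
    w = widths or DEFAULT_WIDTHS[name]
    return ArchitectureSpec(
        name=name, input_size=input_size, input_channels=input_channels,
        encoder_widths=tuple(w["encoder"]), decoder_widths=tuple(w["decoder"]))


@dataclass
class ModelProfile:
    """Analytic complexity summary at the declared input size."""

    parameter_count: int = 0
    flop_count: int = 0

    @property
    def params_million(self) -> float:
        return round(self.parameter_count / 1e6, 1)

    @property
    def gflops(self) -> float:
        return round(self.flop_count / 1e9, 1)


def relative_increase(value: float, base: float) -> float:
    """Percent increase of ``value`` over ``base``, one decimal."""
    return round(100.0 * (value - base) / base, 1)


# ---------------------------------------------------------------------------
# Layer trace: shared source of truth for the analytic profiler.
# ---------------------------------------------------------------------------

def _conv_entry(name, kh, kw, cin_pg, cout, h, w, weights, bias):
    return {"kind": "conv", "name": name, "kh": kh, "kw": kw, "cin_pg": cin_pg,
            "cout": cout, "hout": h, "wout": w, "weights": weights, "bias": bias}


def _sspdc_entries(name, cin, cout, h, w):
    out = []
    for d in (1, 2, 3):
        out.append(_conv_entry(f"{name}.dw{d}", 3, 3, 1, cin, h, w, 9 * cin, 0))
    out.append(_conv_entry(f"{name}.pw", 1, 1, 3 * cin, cout, h, w,
                           3 * cin * cout, cout))
    out.append({"kind": "bn", "name": f"{name}.bn", "c": cout, "hout": h, "wout": w,
                "weights": 2 * cout})
    out.append({"kind": "elementwise", "name": f"{name}.relu", "count": h * w * cout,
                "weights": 0})
    return out


def _lha_entry(name, c, h, w):
    # channel gate: max+avg pools (2*HWC), 1-D conv (6C) + bias (C) + sigmoid (C),
    # gating (HWC); spatial gate: max+avg (2*HWC), 7x7 conv (2*49*HW) + bias +
    # sigmoid (2*HW), add (HW), gating (HWC)
    flops = 6 * h * w * c + 8 * c + (2 * 49 + 3) * h * w
    return {"kind": "lha", "name": name, "count": flops, "weights": 54}


def _elem(name, count):
    return {"kind": "elementwise", "name": name, "count": count, "weights": 0}


def layer_trace(spec: ArchitectureSpec, input_size: int | None = None) -> list[dict]:
    """Per-layer cost descriptors for ``spec`` at ``input_size``.

    Purely arithmetic -- no weight arrays are allocated. Resolution halves
    after each encoder stage and doubles after each decoder stage; conv
    stacks run at their stage's input resolution.
    """
    s = input_size or spec.input_size
    if s % 16:
        raise ValueError("input size must be divisible by 16")
    trace: list[dict] = []
    r = s
    cin = spec.input_channels
    for k, st in enumerate(spec.encoder_stages):
        trace.append(_lha_entry(f"enc{k + 1}.lha", cin, r, r))
        widths = [st.in_width] + [st.out_width] * st.conv_count
        for i in range(st.conv_count):
            trace.extend(_sspdc_entries(f"enc{k + 1}.conv{i + 1}", widths[i],
                                        widths[i + 1], r, r))
        r //= 2
        trace.append(_elem(f"enc{k + 1}.pool", r * r * st.out_width))
        cin = st.out_width
    kind = "unpool" if spec.name == "lw_segnet" else "upsample"
    for k, st in enumerate(spec.decoder_stages):
        # the last LW-Segnet decoder unpools first so its convs densify the
        # sparse map at full resolution before the classifier
        last_segnet = spec.name == "lw_segnet" and k == 3
        if last_segnet:
            r *= 2
            trace.append(_elem(f"dec{k + 1}.{kind}", r * r * st.in_width))
        trace.append(_lha_entry(f"dec{k + 1}.lha", st.in_width, r, r))
        widths = [st.in_width] + [st.out_width] * st.conv_count
        for i in range(st.conv_count):
            trace.extend(_sspdc_entries(f"dec{k + 1}.conv{i + 1}", widths[i],
                                        widths[i + 1], r, r))
        if not last_segnet:
            r *= 2
            trace.append(_elem(f"dec{k + 1}.{kind}", r * r * st.out_width))
    trace.append(_conv_entry("head.pw", 1, 1, spec.head_in_width, spec.classes,
                             r, r, spec.head_in_width * spec.classes, spec.classes))
    trace.append(_elem("head.softmax", r * r * spec.classes))
    assert r == s
    return trace


def entry_flops(e: dict) -> int:
    """FLOPs of one trace entry (1 MAC = 2 FLOPs for convolutions)."""
    if e["kind"] == "conv":
        return 2 * e["kh"] * e["kw"] * e["cin_pg"] * e["cout"] * e["hout"] * e["wout"]
    if e["kind"] == "bn":
        return e["c"] * e["hout"] * e["wout"]
    return e["count"]


def count_parameters(spec: ArchitectureSpec) -> ModelProfile:
    """Analytic trainable-parameter total (input-size independent)."""
    total = 0
    for e in layer_trace(spec, spec.input_size):
        total += e.get("weights", 0) + e.get("bias", 0)
    return ModelProfile(parameter_count=total)


def count_flops(spec: ArchitectureSpec, input_size: int | None = None) -> ModelProfile:
    """Analytic FLOP total for one forward pass at ``input_size``."""
    total = sum(entry_flops(e) for e in layer_trace(spec, input_size))
    return ModelProfile(parameter_count=count_parameters(spec).parameter_count,
                        flop_count=total)


def profile(spec: ArchitectureSpec, input_size: int | None = None) -> ModelProfile:
    return count_flops(spec, input_size)


# ---------------------------------------------------------------------------
# Model assembly.
# ---------------------------------------------------------------------------

class _Stage:
    """One encoder/decoder stage: LHA gate + SSPDC conv stack."""

    def __init__(self, spec: StageSpec, rng: np.random.Generator) -> None:
        self.lha = LHA(rng)
        widths = [spec.in_width] + [spec.out_width] * spec.conv_count
        self.convs = [SSPDC(widths[i], widths[i + 1], rng)
                      for i in range(spec.conv_count)]

    def layers(self) -> list[Layer]:
        return [self.lha] + list(self.convs)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = self.lha.forward(x, train)
        for c in self.convs:
            x = c.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for c in reversed(self.convs):
            g = c.backward(g)
        return self.lha.backward(g)


class SegmentationModel:
    """Common surface of both networks: params, forward to logits, backward.

    ``input_mean`` / ``input_std`` hold per-band standardisation statistics
    (identity until set by training); they are applied to every input so
    checkpointed models normalise test tiles exactly as they normalised
    training tiles.
    """

    spec: ArchitectureSpec

    def set_normalization(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.input_mean = np.asarray(mean, dtype=np.float32).reshape(-1)
        self.input_std = np.asarray(std, dtype=np.float32).reshape(-1)
        if self.input_mean.size != self.spec.input_channels or np.any(self.input_std <= 0):
            raise ValueError("need one positive std and one mean per band")

    def params(self) -> list[Param]:
        return [p for layer in self._all_layers for p in layer.params()]

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected (N, {self.spec.input_channels}, H, W) input, got {x.shape}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input height and width must be divisible by 16")
        mean = getattr(self, "input_mean", None)
        if mean is not None:
            x = (x - mean[None, :, None, None]) / self.input_std[None, :, None, None]
        return x


class LWSegnet(SegmentationModel):
    """Encoder--decoder with pooling-index (sparse) unpooling skips."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator) -> None:
        if spec.name != "lw_segnet":
            raise ValueError("spec.name must be 'lw_segnet'")
        self.spec = spec
        self.enc = [_Stage(s, rng) for s in spec.encoder_stages]
        self.pools = [MaxPool2x2() for _ in range(4)]
        self.dec = [_Stage(s, rng) for s in spec.decoder_stages]
        # decoder stage k unpools with the indices of encoder stage 4-k
        self.unpools = [MaxUnpool2x2(self.pools[3 - k]) for k in range(4)]
        self.head = PointwiseConv(spec.head_in_width, spec.classes, rng)
        self._all_layers = [l for st in self.enc + self.dec for l in st.layers()] + [self.head]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = self._check_input(x)
        for stage, pool in zip(self.enc, self.pools):
            x = pool.forward(stage.forward(x, train), train)
        for k, (stage, unpool) in enumerate(zip(self.dec, self.unpools)):
            if k == 3:  # final stage densifies after unpooling
                x = stage.forward(unpool.forward(x, train), train)
            else:
                x = unpool.forward(stage.forward(x, train), train)
        return self.head.forward(x, train)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        for k in range(3, -1, -1):
            if k == 3:
                g = self.unpools[k].backward(self.dec[k].backward(g))
            else:
                g = self.dec[k].backward(self.unpools[k].backward(g))
        for stage, pool in zip(reversed(self.enc), reversed(self.pools)):
            g = stage.backward(pool.backward(g))


class LWUnet(SegmentationModel):
    """Symmetric encoder--decoder with concatenation skips and bilinear upsampling."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator) -> None:
        if spec.name != "lw_unet":
            raise ValueError("spec.name must be 'lw_unet'")
        self.spec = spec
        self.enc = [_Stage(s, rng) for s in spec.encoder_stages]
        self.pools = [MaxPool2x2() for _ in range(4)]
        self.dec = [_Stage(s, rng) for s in spec.decoder_stages]
        self.ups = [BilinearUp2x() for _ in range(4)]
        self.head = PointwiseConv(spec.head_in_width, spec.classes, rng)
        self._all_layers = [l for st in self.enc + self.dec for l in st.layers()] + [self.head]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = self._check_input(x)
        self._skip_channels = []
        skips = []
        for stage, pool in zip(self.enc, self.pools):
            x = stage.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        self._skips = skips
        for k, (stage, up) in enumerate(zip(self.dec, self.ups)):
            if k > 0:
                skip = skips[4 - k]
                self._skip_channels.append(skip.shape[1])
                x = np.concatenate([x, skip], axis=1)
            x = up.forward(stage.forward(x, train), train)
        self._skip_channels.append(skips[0].shape[1])
        x = np.concatenate([x, skips[0]], axis=1)
        return self.head.forward(x, train)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        c_skip = self._skip_channels[-1]
        g, skip_grads = g[:, :-c_skip], [g[:, -c_skip:]]  # grad into enc stage 1 output
        enc_extra: list[np.ndarray | None] = [skip_grads[0], None, None, None]
        for k in range(3, -1, -1):
            g = self.dec[k].backward(self.ups[k].backward(g))
            if k > 0:
                c_skip = self._skip_channels[k - 1]
                enc_extra[4 - k] = g[:, -c_skip:]
                g = g[:, :-c_skip]
        for k in range(3, -1, -1):
            g = self.pools[k].backward(g)
            if enc_extra[k] is not None:
                g = g + enc_extra[k]
            g = self.enc[k].backward(g)


def build_lw_segnet(spec: ArchitectureSpec | None = None, seed: int = 0) -> LWSegnet:
    """Assemble an LW-Segnet; weights drawn from a seeded generator."""
    spec = spec or default_spec("lw_segnet")
    return LWSegnet(spec, np.random.default_rng(seed))


def build_lw_unet(spec: ArchitectureSpec | None = None, seed: int = 0) -> LWUnet:
    """Assemble an LW-Unet; weights drawn from a seeded generator."""
    spec = spec or default_spec("lw_unet")
    return LWUnet(spec, np.random.default_rng(seed))


def build_model(spec: ArchitectureSpec, seed: int = 0) -> SegmentationModel:
    if spec.name == "lw_segnet":
        return build_lw_segnet(spec, seed)
    return build_lw_unet(spec, seed)


def forward_segment(model: SegmentationModel, tile: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability for one ``(H, W, C)`` tile.

    The softmax head produces two class probabilities per pixel; channel 1 is
    the foreground (seedling / row) probability. Thresholding at 0.5 gives
    the predicted binary mask.
    """
    tile = np.asarray(tile, dtype=np.float32)
    if tile.ndim != 3 or tile.shape[2] != model.spec.input_channels:
        raise ValueError(
            f"expected (H, W, {model.spec.input_channels}) tile, got {tile.shape}")
    x = tile.transpose(2, 0, 1)[None]
    logits = model.forward(x, train=False)
    return softmax_channel(logits)[0, 1]
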