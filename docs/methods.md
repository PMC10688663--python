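# Methods

`lwseg` implements two lightweight encoder–decoder convolutional networks for
binary segmentation of rice seedlings in 5-band UAV imagery — per-plant
("stand") detection and plantation-row extraction — together with the loss,
metrics, data pipeline, an analytic efficiency profiler, and a synthetic
paddy-field generator that stands in for the (non-public) UAV scenes. The
networks, backpropagation and the Adam optimiser are implemented directly in
NumPy; every layer is a pair of explicit forward/backward passes, which keeps
the whole computation inspectable and exactly reproducible from a seed.

## Building blocks

**LHA (lightweight hybrid attention).** Each stage is gated before its
convolutions by two sigmoid attentions applied multiplicatively in sequence.
The *channel* gate reduces each band to its global max and mean, passes the
two length-C vectors through a shared 1×3 one-dimensional convolution along
the channel axis (zero-padded at the ends; by linearity this equals
convolving their sum), adds a scalar bias and a sigmoid. The *spatial* gate
adds the channel-wise max and mean maps of the channel-gated tensor, applies
a same-padded 7×7 convolution and a sigmoid. Both gates lie strictly in
(0, 1), so the module never amplifies an activation. The composition order
(channel first, then spatial computed on the gated tensor) and the shared
1-D kernel are design choices; per-path kernels would be equally plausible.

**SSPDC (separable spatial pyramid dilated convolution).** Every
"convolution" in both networks is a three-branch depthwise pyramid: 3×3
depthwise kernels at dilation rates 1, 2 and 3, i.e. effective receptive
fields of 3, 5 and 7 pixels (2d+1). Dense 5×5/7×7 kernels would defeat the
lightweight purpose; dilation reaches the same field at 9 taps per channel.
Branch outputs are concatenated channel-wise (depth 3·C_in) and fused by a
pointwise 1×1 convolution with bias, followed by batch normalisation and
ReLU inside encoder/decoder stages. The classifier head is a plain 1×1
convolution to 2 classes with softmax and no ReLU.

**Pooling, unpooling, upsampling.** Downsampling is 2×2 stride-2 max pooling;
ties break to the first occurrence in row-major window order, making every
index deterministic and testable. LW-Segnet's pools store argmax indices and
its decoder places values back sparsely at those positions (zeros
elsewhere). LW-Unet upsamples with parameter-free bilinear interpolation
under the half-pixel-center convention (output j reads source coordinate
(j+0.5)/2 − 0.5, clamped) — pinned by a ramp test: upsampling (0, 1) gives
(0, 0.25, 0.75, 1).

## Architectures

Both networks have four encoder and four decoder stages over 5-band input;
each stage is `LHA → conv stack → down/up-sampling`. Input sizes must be
divisible by 16 (four halvings); odd sizes are rejected at build/forward
time rather than padded.

* **LW-Segnet** uses (2, 1, 1, 5) convolutions per encoder stage and
  (5, 1, 1, 2) per decoder stage, with pooling-index unpooling. Decoder
  stage k reuses the indices of encoder stage 5−k. The first three decoder
  stages run their convolutions at the stage's input (coarser) resolution
  and unpool afterwards, which places the heavy five-conv stack at 1/16
  resolution; the *last* decoder stage unpools first and runs its two
  convolutions at full resolution so the sparse map is densified before the
  classifier. (With a 1×1 head directly on an unpooled map, three quarters
  of all pixels would share one constant logit — measured desk-scale
  ceilings near IoU 0.3 — so the final stage must convolve after
  upsampling.)
* **LW-Unet** uses 2 convolutions per stage, plain max pooling, and bilinear
  upsampling at the end of each decoder unit. Decoder unit 1 consumes the
  encoder chain output at 1/16 resolution; each later unit concatenates the
  upsampled previous output with the matching-resolution pre-pool encoder
  output, and the stage-1 skip is concatenated just before the classifier.
  All four skips are used; fusion is concatenation, never addition.

**Channel widths.** The per-stage widths are explicit configuration. The
shipped defaults — LW-Segnet encoder (32, 64, 80, 216), decoder
(880, 112, 72, 16); LW-Unet encoder (16, 24, 80, 232), decoder
(1680, 88, 64, 24) — were calibrated once, with the analytic profiler only,
so that the models land on the published complexity budgets (11.0 M
parameters / 36.8 GFLOPs and 10.6 M / 32.1 GFLOPs at 512×512×5), and are
frozen. Mirrored encoder/decoder ladders cannot reach those joint budgets
under any FLOP convention: the published FLOP-per-parameter ratio (~3.3 k)
forces most parameters below 1/16 resolution, hence the wide first decoder
stage. A consequence of non-mirrored widths is that per-channel pooling
indices are undefined at the decoder; each pool therefore also records a
channel-shared window argmax (of the channel-mean activation) that the
unpool broadcasts when widths differ. Per-channel semantics are preserved
whenever widths match, and in the functional block API. A narrow
`COMPACT_WIDTHS` ladder (8, 16, 32, 48)/(64, 32, 16, 8) is provided for
CPU-scale experiments.

## Profiler

`count_parameters` and `count_flops` are analytic: both derive from a single
per-layer trace computed from the architecture spec without allocating
weights, and the parameter total is asserted equal (exact integer equality)
to the built model's own array-size tally. FLOP convention: one
multiply-accumulate = 2 FLOPs; a convolution costs
2·K_h·K_w·C_in_per_group·C_out·H_out·W_out; batch norm, ReLU, pooling,
unpooling, interpolation and softmax cost 1 FLOP per output element; the
channel-attention 1-D convolution costs O(C) independent of the spatial
size, which is why FLOPs scale with input area as 4× only up to a ~1e−6
relative term. The comparison utility reports percent complexity increase
to one decimal, e.g. a 58.7-GFLOPs profile is +82.9 % over a 32.1-GFLOPs
one.

## Loss and metrics

Training minimises the focal-weighted binary cross-entropy

L = −(1/n) Σ [ α(1−p)^γ · y·log p + (1−α)p^γ · (1−y)·log(1−p) ]

with α = 0.25 and γ = 2 by default and probabilities clipped to
[1e−7, 1−1e−7] before logarithms (the gradient is zeroed outside the clip
range). At γ = 0, α = 0.5 it reduces exactly to half the plain BCE. The
foreground probability is softmax channel 1; predictions threshold at 0.5.

Evaluation pools TP/FP/FN/TN over all tiles of a partition and computes
precision, recall, IoU, F1 and overall accuracy once on the pooled counts
(micro-averaging; per-tile macro reports are available behind a flag). mIoU
is the unweighted mean of the foreground and background IoUs. Zero
denominators follow the agreement convention: a foreground metric with an
empty denominator is 1 when TP = FP = FN = 0, else 0 (symmetrically for the
background IoU). IoU ≡ F1/(2−F1) is asserted to machine precision.

## Data pipeline

Radiometric conversion is the per-band affine map L = gain·DN + bias. Scenes
are cut into a non-overlapping row-major grid of full 512×512 tiles (edge
remnants dropped by default; mirror-padding optional). The 6:1:3
train/validation/test split shuffles ids with a seed and assigns
round-half-up(0.6N) and round-half-up(0.1N) with the test set taking the
remainder — for N = 3,800 exactly 2,280/380/1,140 — stratified per scene
when several scenes are supplied. Augmentation applies flips, right-angle
rotations, and a mild rescale-resample (factor 0.8–1.25, nearest-neighbour
for masks, centre crop/pad back) identically to image and masks. On disk:
multiband TIFF tiles, {0, 255} PNG masks, CSV manifest.

## Synthetic paddy fields

The generator emulates machine-transplanted paddy at the seedling stage:
straight rows with a 300 mm period and 150 mm in-row spacing at 20 mm/px GSD
(15 px and 7.5 px), optional row angle, per-hole dropout, ≤2 px jitter
applied in row coordinates so every plant disk stays inside its row band.
The stand mask is the union of plant disks; the row mask is a solid band of
half-width plant_radius + jitter spanning the surviving plants of each row
(an unplanted row leaves no band), mirroring ground truth produced by
smoothing and connecting seedlings along rows — so stand ⊆ row by
construction and full dropout empties both masks. Spectra are plausible
synthetic defaults in band order (blue, green, red, red-edge, NIR) with
vegetation bright in red-edge/NIR and water dark; glint is modelled as small
saturated clusters in all bands; per-band Gaussian noise is added and the
image clipped to [0, 1]. Three density regimes mirror the study cultivars
(plants per hole 5/3/2 with dropout 0.25/0.10/0.03 and plant radius
3.0/2.5/2.0 px). Per-tile seeds derive from the master seed by a fixed
counter scheme. The generator does not attempt radiative-transfer realism,
growth stages, or the true sensor response; passing tests on it demonstrate
that the pipeline and optimisation behave correctly, not that the published
field accuracies transfer.

## Training

Adam at a constant learning rate (published settings lr 1e−4, batch 32,
50 epochs are the defaults; no schedule or early stopping). Inputs are
standardised per band with statistics of the training tiles, stored on the
model and in checkpoints so evaluation normalises identically. All
randomness — initialisation (He-normal from a seeded generator), shuffling,
tile synthesis — derives from config seeds; two runs with the same config
produce bit-identical loss sequences. Checkpoints are single `.npz` files
holding weights, batch-norm statistics, normalisation, the architecture
spec, the config and the metric history.

Desk-scale runs (CPU, NumPy) use the compact ladder on 64×64 tiles with
lr 1e−2: a one-batch overfit on 8 easy synthetic tiles passes IoU 0.9 within
200 Adam steps, and a 15-epoch run on 100 tiles (60/10/30 split) reaches
pooled test F1 ≥ 0.8. LW-Unet converges fastest and is used for these
end-to-end checks; LW-Segnet's sparse-index decoding trains markedly slower
at this scale, so its smoke test asserts the decreasing loss trend
(3-epoch moving average) rather than an IoU level. These problem sizes are
the package's desk-scale study conditions; the published 512×512/50-epoch
GPU training is out of reach of a NumPy CPU run and its accuracy tables are
not reproduced.

## Known limitations

* The per-stage widths of the original networks are not public; the shipped
  ladders reproduce the published parameter/FLOP budgets, not necessarily
  the authors' exact configuration.
* The channel-shared unpooling index is a necessary generalisation of
  per-channel index reuse to unequal encoder/decoder widths.
* Softmax over two classes is algebraically a sigmoid on the logit
  difference; the two-channel head is kept for fidelity to the design.
* The engine is float32 and single-threaded NumPy; it is meant for
  correctness and desk-scale experiments, not production training speed.
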