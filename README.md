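# lwseg — lightweight rice-seedling segmentation from 5-band UAV imagery

Counting rice stands and mapping plantation rows right after machine
transplanting is one of the few windows where a grower can still re-plant
missed holes, so the segmentation has to run close to the sensor — on the
UAV or an edge box — which rules out heavyweight backbones. `lwseg`
implements two lightweight encoder–decoder networks for exactly this
setting, for agronomists and remote-sensing engineers working with 5-band
(blue, green, red, red-edge, NIR) multispectral tiles over flooded paddy:

* **LW-Segnet** — four encoders with (2, 1, 1, 5) convolutions and four
  decoders with (5, 1, 1, 2), SegNet-style sparse unpooling driven by stored
  max-pooling argmax indices;
* **LW-Unet** — a symmetric 2-convs-per-stage network with parameter-free
  bilinear upsampling and U-Net concatenation skips.

Both are built from two bespoke blocks. The **LHA** (lightweight hybrid
attention) module gates each stage with a channel attention (global max +
mean per band → shared 1×3 1-D convolution → sigmoid) followed by a spatial
attention (channel max + mean maps added → 7×7 convolution → sigmoid). The
**SSPDC** (separable spatial pyramid dilated convolution) replaces every
dense convolution with three depthwise 3×3 branches at dilation rates
1/2/3 — effective receptive fields 3/5/7 — concatenated and fused by a
pointwise 1×1 convolution, then batch norm and ReLU.

Training minimises the focal-weighted binary cross-entropy

    L = −(1/n) Σ [ α(1−p)^γ y log p + (1−α) p^γ (1−y) log(1−p) ],   α = 0.25, γ = 2

with Adam, and evaluation reports pixel precision, recall, IoU
(TP/(TP+FP+FN)), F1 (2TP/(2TP+FP+FN)), overall accuracy and mIoU from
pooled confusion counts. Everything — networks, backprop, Adam — is plain
NumPy with explicit forward/backward passes, bit-reproducible from a seed.

The package also ships the raster pipeline (radiometric conversion
L = gain·DN + bias, 512×512 tiling, seeded 6:1:3 splitting, flip/rotate/
resample augmentation), an analytic parameter/FLOP profiler, and a synthetic
paddy-field generator (300 mm × 150 mm transplanting geometry at 20 mm/px,
three density regimes, water background with specular glint) so the whole
system is trainable and testable without the original UAV scenes.

## Worked example

```python
from lwseg import architectures as A
from lwseg.datapipe import split_dataset
from lwseg.synthfield import FieldSimConfig, make_dataset
from lwseg.train import TrainConfig, evaluate, train

# analytic efficiency profile of the full-width networks
for name in ("lw_segnet", "lw_unet"):
    prof = A.count_flops(A.default_spec(name), 512)
    print(f"{name}: {prof.params_million} M parameters, {prof.gflops} GFLOPs @ 512x512x5")
print("complexity increase of a 58.7-GFLOPs model over LW-Unet:",
      A.relative_increase(58.7, 32.1), "%")

# desk-scale end-to-end run on synthetic paddy tiles
field = FieldSimConfig(tile_size=64, glint_rate=0.0, plant_radius=3.0, seed=11)
tiles = make_dataset(field, 100, density_regime="medium")
split = split_dataset([t.tile_id for t in tiles], seed=0)
for t in tiles:
    t.split = split.mapping[t.tile_id]

cfg = TrainConfig(architecture="lw_unet", task="stand", learning_rate=1e-2,
                  batch_size=8, epochs=15, seed=0, widths=A.COMPACT_WIDTHS)
model, log = train(cfg, tiles)
loss, report = evaluate(model, [t for t in tiles if t.split == "test"], "stand")
print("network\tprecision%\trecall%\tIoU%\tF1")
print(report.as_table_row("lw_unet"))
```

prints (about a minute on one CPU):

```
lw_segnet: 11.0 M parameters, 36.8 GFLOPs @ 512x512x5
lw_unet: 10.6 M parameters, 32.1 GFLOPs @ 512x512x5
complexity increase of a 58.7-GFLOPs model over LW-Unet: 82.9 %
network	precision%	recall%	IoU%	F1
lw_unet	99.96	97.78	97.74	0.99
```

The profile lines are the analytic complexity of the two full-width
networks (the shipped width ladders are calibrated to these budgets; the
totals are asserted equal to the built models' own parameter tallies). The
last line is a micro-averaged test-set row — precision/recall/IoU in
percent and F1 — for a compact LW-Unet trained for 15 epochs on 60
synthetic tiles and evaluated on the 30 held-out test tiles: on
easy-contrast synthetic paddy the stand-detection task is essentially
solved, which validates the pipeline and the optimiser, not field
performance on real imagery.

The same workflow is available from a shell:

```bash
lwseg simulate --n 100 --regime medium --seed 0 --out tiles/
lwseg train --config train.yaml --out model.ckpt.npz
lwseg eval --ckpt model.ckpt.npz --manifest tiles/manifest.csv --split test
lwseg predict --ckpt model.ckpt.npz --image tiles/synth_medium_0000.tif --out mask.png
lwseg profile --arch lw_unet --input 512
```

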