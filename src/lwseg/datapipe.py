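"""Radiometric conversion, raster tiling, dataset splitting and augmentation.

The pipeline turns a large multiband scene (5-band reflectance or
digital-number raster) plus binary ground-truth masks into aligned
``512 x 512`` training tiles:

* ``to_radiance`` applies the per-band sensor calibration ``L = gain*DN + bias``;
* ``tile_scene`` cuts a non-overlapping row-major grid of full tiles (partial
  edge tiles are dropped by default);
* ``split_dataset`` shuffles tile ids with a seed and assigns
  train/validation/test partitions at the 6:1:3 ratio, rounding half-up on
  the train and validation counts with the test set taking the remainder;
* ``augment`` applies flips, right-angle rotations and mild rescale-resample
  identically to the image and both masks.

On disk, tiles are plain multiband TIFF, masks are single-band PNG with
values {0, 255} (mapped to {0, 1} in memory), and the manifest is a CSV with
one row per tile (id, scene, origin, split).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.transform import rescale

TILE = 512

__all__ = [
    "RadiometricParams",
    "TileRecord",
    "SplitAssignment",
    "to_radiance",
    "tile_scene",
    "split_dataset",
    "augment",
    "write_tiles",
    "read_tiles",
]


@dataclass(frozen=True)
class RadiometricParams:
    """Per-band gain and bias of the sensor calibration."""

    gain: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gain", np.atleast_1d(np.asarray(self.gain, float)))
        object.__setattr__(self, "bias", np.atleast_1d(np.asarray(self.bias, float)))
        if self.gain.shape != self.bias.shape:
            raise ValueError("gain and bias must have one value per band")
        if not (np.isfinite(self.gain).all() and np.isfinite(self.bias).all()):
            raise ValueError("gain and bias must be finite")


def to_radiance(dn: np.ndarray, params: RadiometricParams) -> np.ndarray:
    """Affine radiometric conversion ``L = gain * DN + bias``, per band.

    ``dn`` is ``(H, W, bands)`` (or ``(H, W)`` with single-band params).
    """
    dn = np.asarray(dn, dtype=np.float64)
    bands = dn.shape[2] if dn.ndim == 3 else 1
    if bands != params.gain.size:
        raise ValueError(f"{bands} bands but {params.gain.size} calibration entries")
    return dn * params.gain + params.bias


@dataclass
class TileRecord:
    """One image tile with its paired masks and provenance."""

    tile_id: str
    image: np.ndarray                  # (tile, tile, 5) float32
    stand_mask: np.ndarray             # (tile, tile) uint8 in {0, 1}
    row_mask: np.ndarray               # (tile, tile) uint8 in {0, 1}
    origin: tuple[int, int] = (0, 0)
    scene: str = ""
    split: str = "unassigned"

    def validate(self) -> None:
        h, w = self.image.shape[:2]
        if self.stand_mask.shape != (h, w) or self.row_mask.shape != (h, w):
            raise ValueError("masks must align with the image")
        for m in (self.stand_mask, self.row_mask):
            if not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be binary")
        if min(self.origin) < 0:
            raise ValueError("origin must be nonnegative")


def tile_scene(image: np.ndarray, stand_mask: np.ndarray,
               row_mask: np.ndarray | None = None, tile: int = TILE,
               scene: str = "scene", pad_edges: bool = False) -> list[TileRecord]:
    """Cut a scene into a non-overlapping row-major grid of full tiles.

    Edge remnants smaller than ``tile`` are dropped unless ``pad_edges`` is
    set, in which case the scene is mirror-padded up to a whole number of
    tiles first. Masks are cut with identical offsets.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("scene image must be (H, W, bands)")
    if row_mask is None:
        row_mask = np.zeros(image.shape[:2], dtype=np.uint8)
    stand_mask = np.asarray(stand_mask)
    row_mask = np.asarray(row_mask)
    h, w = image.shape[:2]
    if h < tile or w < tile:
        raise ValueError(f"scene {h}x{w} is smaller than one {tile}x{tile} tile")
    if pad_edges:
        ph, pw = (-h) % tile, (-w) % tile
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        stand_mask = np.pad(stand_mask, ((0, ph), (0, pw)), mode="reflect")
        row_mask = np.pad(row_mask, ((0, ph), (0, pw)), mode="reflect")
        h, w = image.shape[:2]
    records = []
    for i in range(h // tile):
        for j in range(w // tile):
            r, c = i * tile, j * tile
            rec = TileRecord(
                tile_id=f"{scene}_{i:03d}_{j:03d}",
                image=np.ascontiguousarray(image[r:r + tile, c:c + tile], dtype=np.float32),
                stand_mask=np.ascontiguousarray(stand_mask[r:r + tile, c:c + tile], dtype=np.uint8),
                row_mask=np.ascontiguousarray(row_mask[r:r + tile, c:c + tile], dtype=np.uint8),
                origin=(r, c), scene=scene)
            rec.validate()
            records.append(rec)
    return records


@dataclass(frozen=True)
class SplitAssignment:
    """Tile-id to partition mapping at fixed ratios, reproducible from the seed."""

    mapping: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int
    counts: dict[str, int] = field(default_factory=dict)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(tile_ids: list[str], ratios: tuple[float, float, float] = (0.6, 0.1, 0.3),
                  seed: int = 0, by_scene: dict[str, str] | None = None) -> SplitAssignment:
    """Seeded 6:1:3 train/validation/test assignment.

    Counts are ``round_half_up(r_train * N)`` and ``round_half_up(r_val * N)``
    with the test partition taking the remainder. When ``by_scene`` maps tile
    ids to scene names the split is stratified per scene.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    ids = list(tile_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("tile ids must be unique")
    groups: dict[str, list[str]]
    if by_scene:
        groups = {}
        for t in ids:
            groups.setdefault(by_scene[t], []).append(t)
    else:
        groups = {"": ids}
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    for _, members in sorted(groups.items()):
        perm = [members[i] for i in rng.permutation(len(members))]
        n = len(perm)
        n_tr = _round_half_up(ratios[0] * n)
        n_va = _round_half_up(ratios[1] * n)
        for t in perm[:n_tr]:
            mapping[t] = "train"
        for t in perm[n_tr:n_tr + n_va]:
            mapping[t] = "validation"
        for t in perm[n_tr + n_va:]:
            mapping[t] = "test"
    counts = {s: sum(1 for v in mapping.values() if v == s)
              for s in ("train", "validation", "test")}
    return SplitAssignment(mapping=mapping, ratios=tuple(ratios), seed=seed, counts=counts)


def _resample(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Rescale then center-crop/pad back to the original shape."""
    h, w = arr.shape[:2]
    channel_axis = 2 if arr.ndim == 3 else None
    out = rescale(arr.astype(np.float32), factor, order=order, mode="reflect",
                  channel_axis=channel_axis, anti_aliasing=False)
    nh, nw = out.shape[:2]
    if nh >= h:
        r0, c0 = (nh - h) // 2, (nw - w) // 2
        out = out[r0:r0 + h, c0:c0 + w]
    else:
        pr, pc = h - nh, w - nw
        pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2))
        out = np.pad(out, pad + (((0, 0),) if arr.ndim == 3 else ()), mode="reflect")
    return out


_FLIP_OPS = {
    "hflip": lambda a: a[:, ::-1],
    "vflip": lambda a: a[::-1],
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
}


def augment(record: TileRecord, plan: list,
            resample_factor: float = 1.1) -> list[TileRecord]:
    """Apply a plan of geometric ops, each yielding one new record.

    Plan entries are op names (``hflip``, ``vflip``, ``rot90``, ``rot180``,
    ``rot270``, ``resample``) or ``("resample", factor)`` with the factor in
    [0.8, 1.25]. Every op is applied identically to the image and both masks;
    masks are resampled with nearest-neighbour interpolation so they stay
    binary.
    """
    if not plan:
        raise ValueError("augmentation plan must be nonempty")
    out = []
    for entry in plan:
        name, factor = (entry, resample_factor) if isinstance(entry, str) else entry
        if name in _FLIP_OPS:
            op = _FLIP_OPS[name]
            img = np.ascontiguousarray(op(record.image))
            sm = np.ascontiguousarray(op(record.stand_mask))
            rm = np.ascontiguousarray(op(record.row_mask))
        elif name == "resample":
            if not 0.8 <= factor <= 1.25:
                raise ValueError("resample factor must be in [0.8, 1.25]")
            img = _resample(record.image, factor, order=1).astype(np.float32)
            sm = _resample(record.stand_mask, factor, order=0).astype(np.uint8)
            rm = _resample(record.row_mask, factor, order=0).astype(np.uint8)
        else:
            raise ValueError(f"unknown augmentation op {name!r}")
        rec = replace(record, tile_id=f"{record.tile_id}_{name}",
                      image=img, stand_mask=sm, row_mask=rm)
        rec.validate()
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# On-disk tile store: TIFF image + PNG masks + CSV manifest.
# ---------------------------------------------------------------------------

def write_tiles(records: list[TileRecord], out_dir: str) -> str:
    """Write tiles and the manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in records:
        rec.validate()
        tifffile.imwrite(os.path.join(out_dir, f"{rec.tile_id}.tif"),
                         rec.image.astype(np.float32))
        iio.imwrite(os.path.join(out_dir, f"{rec.tile_id}_stand.png"),
                    (rec.stand_mask * 255).astype(np.uint8))
        iio.imwrite(os.path.join(out_dir, f"{rec.tile_id}_row.png"),
                    (rec.row_mask * 255).astype(np.uint8))
        rows.append({"tile_id": rec.tile_id, "scene": rec.scene,
                     "origin_row": rec.origin[0], "origin_col": rec.origin[1],
                     "split": rec.split})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_tiles(manifest_path: str, split: str | None = None) -> list[TileRecord]:
    """Load tile records listed in a manifest, optionally one partition only."""
    df = pd.read_csv(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    records = []
    for _, row in df.iterrows():
        if split is not None and row["split"] != split:
            continue
        tid = row["tile_id"]
        image = tifffile.imread(os.path.join(base, f"{tid}.tif")).astype(np.float32)
        sm = (np.asarray(iio.imread(os.path.join(base, f"{tid}_stand.png"))) > 127)
        rm = (np.asarray(iio.imread(os.path.join(base, f"{tid}_row.png"))) > 127)
        rec = TileRecord(tile_id=tid, image=image,
                         stand_mask=sm.astype(np.uint8), row_mask=rm.astype(np.uint8),
                         origin=(int(row["origin_row"]), int(row["origin_col"])),
                         scene=str(row["scene"]), split=str(row["split"]))
        rec.validate()
        records.append(rec)
    return records
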