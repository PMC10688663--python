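"""Training, evaluation and checkpointing for the two segmentation networks.

Training minimises the focal-weighted binary cross-entropy with Adam at a
constant learning rate (published settings: lr 1e-4, batch size 32,
50 epochs; smoke tests use reduced sizes, both are recorded in the run log).
All randomness -- weight initialisation, shuffling -- derives from the
config seed. Evaluation micro-averages: pixel confusion counts are pooled
over all tiles of a partition and the metrics are computed once on the
pooled counts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .architectures import (
    ArchitectureSpec,
    SegmentationModel,
    build_model,
    default_spec,
    forward_segment,
)
from .datapipe import TileRecord, read_tiles
from .layers import BatchNorm, softmax_channel
from .objectives import (
    ConfusionCounts,
    LossConfig,
    MetricReport,
    confusion,
    metrics,
    wbce_focal_grad,
    wbce_focal_loss,
)

__all__ = ["TrainConfig", "RunLog", "Adam", "train", "evaluate",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    architecture: str = "lw_unet"
    task: str = "stand"                # stand | row
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    manifest: str | None = None
    input_size: int = 512
    input_channels: int = 5
    widths: dict | None = None         # per-path width override

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate > 0, batch_size >= 1, epochs >= 1 required")
        if self.task not in ("stand", "row"):
            raise ValueError("task must be 'stand' or 'row'")

    def spec(self) -> ArchitectureSpec:
        return default_spec(self.architecture, input_size=self.input_size,
                            input_channels=self.input_channels, widths=self.widths)

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha1(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class RunLog:
    config_hash: str
    seed: int
    epochs: list[dict] = field(default_factory=list)
    wall_time_s: float = 0.0

    def append(self, **row) -> None:
        row["epoch"] = len(self.epochs)
        self.epochs.append(row)


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _batch_arrays(records: list[TileRecord], task: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([r.image.transpose(2, 0, 1) for r in records]).astype(np.float32)
    key = "stand_mask" if task == "stand" else "row_mask"
    y = np.stack([getattr(r, key) for r in records]).astype(np.float32)
    return x, y


def _loss_and_grad(model: SegmentationModel, x: np.ndarray, y: np.ndarray,
                   loss_cfg: LossConfig) -> tuple[float, np.ndarray, np.ndarray]:
    """Forward + backward of one batch; returns (loss, fg probability, pred mask)."""
    logits = model.forward(x, train=True)
    prob = softmax_channel(logits)
    p = prob[:, 1]
    loss = wbce_focal_loss(y, p, loss_cfg)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss; aborting")
    dp = wbce_focal_grad(y, p, loss_cfg).astype(np.float32)
    # two-class softmax: p = sigma(z1 - z0) => dp/dz1 = p(1-p) = -dp/dz0
    dz1 = dp * (p * (1.0 - p)).astype(np.float32)
    dlogits = np.stack([-dz1, dz1], axis=1)
    model.zero_grad()
    model.backward(dlogits)
    return loss, p, (p >= 0.5)


def _iou(pred: np.ndarray, truth: np.ndarray) -> float:
    c = confusion(pred.astype(np.uint8), truth.astype(np.uint8))
    return metrics(c).iou


def train(cfg: TrainConfig, records: list[TileRecord] | None = None,
          log_fn=None) -> tuple[SegmentationModel, RunLog]:
    """Train one binary-task model; fully reproducible from ``cfg.seed``.

    ``records`` may carry split assignments in their ``split`` field;
    otherwise they are loaded from ``cfg.manifest``. At least one training
    and one validation tile are required.
    """
    if records is None:
        if cfg.manifest is None:
            raise ValueError("either records or cfg.manifest is required")
        records = read_tiles(cfg.manifest)
    train_recs = [r for r in records if r.split == "train"]
    val_recs = [r for r in records if r.split == "validation"]
    if not train_recs or not val_recs:
        raise ValueError("need at least one training and one validation tile")
    size = train_recs[0].image.shape[0]
    cfg.input_size = size
    model = build_model(cfg.spec(), seed=cfg.seed)
    # per-band standardisation from the training tiles; stored on the model
    # (and in checkpoints) so evaluation normalises identically
    stack = np.stack([r.image for r in train_recs])
    model.set_normalization(stack.mean(axis=(0, 1, 2)),
                            stack.std(axis=(0, 1, 2)) + 1e-6)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    log = RunLog(config_hash=cfg.config_hash(), seed=cfg.seed)
    t0 = time.time()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_recs))
        losses, inter, union = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_recs[i] for i in order[start:start + cfg.batch_size]]
            x, y = _batch_arrays(batch, cfg.task)
            loss, _, pred = _loss_and_grad(model, x, y, cfg.loss)
            opt.step()
            losses.append(loss)
            yb = y.astype(bool)
            inter += int(np.sum(pred & yb))
            union += int(np.sum(pred | yb))
        val_loss, val_report = evaluate(model, val_recs, cfg.task, cfg.loss)
        row = dict(train_loss=float(np.mean(losses)),
                   train_iou=inter / union if union else 1.0,
                   val_loss=val_loss, val_iou=val_report.iou)
        log.append(**row)
        if log_fn:
            log_fn(f"epoch {epoch}: " + " ".join(f"{k}={v:.4f}" for k, v in row.items()))
    log.wall_time_s = time.time() - t0
    return model, log


def evaluate(model: SegmentationModel, records: list[TileRecord], task: str,
             loss_cfg: LossConfig = LossConfig(), macro: bool = False):
    """Pooled (micro-averaged) loss and metrics over a set of tiles.

    With ``macro=True`` additionally returns the per-tile metric reports.
    """
    if not records:
        raise ValueError("no tiles to evaluate")
    counts = ConfusionCounts(0, 0, 0, 0)
    losses = []
    per_tile = []
    key = "stand_mask" if task == "stand" else "row_mask"
    for rec in records:
        p = forward_segment(model, rec.image)
        truth = getattr(rec, key)
        losses.append(wbce_focal_loss(truth, p, loss_cfg))
        c = confusion((p >= 0.5).astype(np.uint8), truth)
        counts = counts + c
        if macro:
            per_tile.append(metrics(c))
    report = metrics(counts)
    if macro:
        return float(np.mean(losses)), report, per_tile
    return float(np.mean(losses)), report


# ---------------------------------------------------------------------------
# Checkpoints: single .npz holding weights, BN statistics, spec and config.
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def _state_arrays(model: SegmentationModel) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.params()):
        state[f"param_{i:04d}"] = p.value
    bn_idx = 0
    for layer in model._all_layers:
        for sub in ([layer] if isinstance(layer, BatchNorm)
                    else getattr(layer, "bn", None) and [layer.bn] or []):
            state[f"bn_{bn_idx:04d}_mean"] = sub.running_mean
            state[f"bn_{bn_idx:04d}_var"] = sub.running_var
            bn_idx += 1
    return state


def save_checkpoint(path: str, model: SegmentationModel, cfg: TrainConfig,
                    log: RunLog | None = None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(cfg),
        "spec": {
            "name": model.spec.name,
            "input_channels": model.spec.input_channels,
            "classes": model.spec.classes,
            "input_size": model.spec.input_size,
            "encoder_widths": list(model.spec.encoder_widths),
            "decoder_widths": list(model.spec.decoder_widths),
        },
        "history": log.epochs if log else [],
        "config_hash": cfg.config_hash(),
    }
    arrays = _state_arrays(model)
    if getattr(model, "input_mean", None) is not None:
        arrays["input_mean"] = model.input_mean
        arrays["input_std"] = model.input_std
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> tuple[SegmentationModel, dict]:
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
    spec = ArchitectureSpec(
        name=meta["spec"]["name"],
        input_channels=meta["spec"]["input_channels"],
        classes=meta["spec"]["classes"],
        input_size=meta["spec"]["input_size"],
        encoder_widths=tuple(meta["spec"]["encoder_widths"]),
        decoder_widths=tuple(meta["spec"]["decoder_widths"]),
    )
    model = build_model(spec, seed=0)
    if "input_mean" in data:
        model.set_normalization(data["input_mean"], data["input_std"])
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"param_{i:04d}"]
    bn_idx = 0
    for layer in model._all_layers:
        for sub in ([layer] if isinstance(layer, BatchNorm)
                    else getattr(layer, "bn", None) and [layer.bn] or []):
            sub.running_mean[...] = data[f"bn_{bn_idx:04d}_mean"]
            sub.running_var[...] = data[f"bn_{bn_idx:04d}_var"]
            bn_idx += 1
    return model, meta
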