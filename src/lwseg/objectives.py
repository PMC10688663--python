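"""Binary cross-entropy, focal-weighted BCE, and pixel-wise evaluation metrics.

The training objective is the weighted focal binary cross-entropy

    L = -(1/n) * sum[ alpha * (1-p)^gamma * y * log p
                      + (1-alpha) * p^gamma * (1-y) * log(1-p) ]

with balancing parameter ``alpha`` (default 0.25) that up-weights the scarce
foreground class and focusing parameter ``gamma`` (default 2) that
down-weights easy pixels. At ``gamma = 0, alpha = 0.5`` it reduces to half
the plain BCE. Probabilities are clipped to ``[eps, 1 - eps]`` before any
logarithm.

Evaluation pools pixel confusion counts (TP/FP/FN/TN) and reports precision,
recall, IoU, F1, overall accuracy and mIoU (the unweighted mean of the
foreground and background IoUs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "ConfusionCounts",
    "MetricReport",
    "bce_loss",
    "wbce_focal_loss",
    "wbce_focal_grad",
    "confusion",
    "metrics",
]


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.25
    gamma: float = 2.0
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 0.0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.eps <= 1e-3:
            raise ValueError("eps must be in (0, 1e-3]")


def _prep(y: np.ndarray, p: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.shape != p.shape or y.size < 1:
        raise ValueError("y and p must be aligned and non-empty")
    return y, np.clip(p, eps, 1.0 - eps)


def bce_loss(y: np.ndarray, p: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy over pixels."""
    y, p = _prep(y, p, eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def wbce_focal_loss(y: np.ndarray, p: np.ndarray,
                    cfg: LossConfig = LossConfig()) -> float:
    """Mean focal-weighted binary cross-entropy over pixels."""
    y, p = _prep(y, p, cfg.eps)
    a, g = cfg.alpha, cfg.gamma
    pos = a * (1.0 - p) ** g * y * np.log(p)
    neg = (1.0 - a) * p ** g * (1.0 - y) * np.log1p(-p)
    return float(-np.mean(pos + neg))


def wbce_focal_grad(y: np.ndarray, p: np.ndarray,
                    cfg: LossConfig = LossConfig()) -> np.ndarray:
    """dL/dp of the focal loss, elementwise, in the shape of ``p``.

    Pixels whose probability lies outside the clip range get zero gradient.
    """
    shape = np.asarray(p).shape
    yf, pc = _prep(y, p, cfg.eps)
    a, g = cfg.alpha, cfg.gamma
    # d/dp [-(a (1-p)^g y log p)] = a y [ g (1-p)^(g-1) log p - (1-p)^g / p ]
    dpos = a * yf * (g * (1.0 - pc) ** (g - 1.0) * np.log(pc) - (1.0 - pc) ** g / pc) \
        if g > 0 else -a * yf / pc
    # d/dp [-((1-a) p^g (1-y) log(1-p))] = (1-a)(1-y) [ -g p^(g-1) log(1-p) + p^g/(1-p) ]
    dneg = (1.0 - a) * (1.0 - yf) * (
        -(g * pc ** (g - 1.0) * np.log1p(-pc) if g > 0 else 0.0) + pc ** g / (1.0 - pc))
    grad = (dpos + dneg) / yf.size
    inside = (np.asarray(p).ravel() > cfg.eps) & (np.asarray(p).ravel() < 1.0 - cfg.eps)
    return np.where(inside, grad, 0.0).reshape(shape)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Pixel tallies of a binary prediction against a binary ground truth."""
    pred = np.asarray(pred_mask)
    truth = np.asarray(truth_mask)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("masks must be binary (0/1)")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    iou: float
    f1: float
    overall_accuracy: float
    miou: float

    def as_table_row(self, name: str = "") -> str:
        """Delimited row in the published layout (percentages, F1 to 2 dp)."""
        return (f"{name}\t{self.precision * 100:.2f}\t{self.recall * 100:.2f}"
                f"\t{self.iou * 100:.2f}\t{self.f1:.2f}")


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Precision, recall, IoU, F1, overall accuracy and mIoU from pooled counts.

    Zero-denominator convention: a foreground metric whose denominator is
    empty is 1 when TP = FP = FN = 0 (empty target met by an empty
    prediction), else 0; symmetrically for the background IoU inside mIoU.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn

    def ratio(num: int, den: int, agree: bool) -> float:
        if den == 0:
            return 1.0 if agree else 0.0
        return num / den

    fg_agree = tp == 0 and fp == 0 and fn == 0
    bg_agree = tn == 0 and fp == 0 and fn == 0
    iou_fg = ratio(tp, tp + fp + fn, fg_agree)
    iou_bg = ratio(tn, tn + fp + fn, bg_agree)
    return MetricReport(
        precision=ratio(tp, tp + fp, fg_agree),
        recall=ratio(tp, tp + fn, fg_agree),
        iou=iou_fg,
        f1=ratio(2 * tp, 2 * tp + fp + fn, fg_agree),
        overall_accuracy=ratio(tp + tn, counts.total, True),
        miou=0.5 * (iou_fg + iou_bg),
    )
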