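"""Confusion-count segmentation metrics, the combined BCE+Dice loss,
multi-seed aggregation and the between-model Welch t-test."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .exceptions import ShapeError
from .nd import Tensor

METRIC_NAMES = ("dice", "ioup", "recall", "acc", "tnr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    dice: float
    ioup: float
    recall: float
    acc: float
    tnr: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between two binary masks of equal shape."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ShapeError(f"mask shapes differ: {pred_mask.shape} vs {gt_mask.shape}")
    for name, m in (("pred", pred_mask), ("gt", gt_mask)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary 0/1")
    p = pred_mask.astype(bool)
    g = gt_mask.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        tn=int(np.sum(~p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Dice, foreground IoU, recall, accuracy and specificity from counts.

    Empty-empty convention: with no foreground in either mask the overlap
    metrics are 1 rather than 0/0.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn

    def ratio(num: int, den: int, empty_value: float = 1.0) -> float:
        return num / den if den > 0 else empty_value

    return MetricReport(
        dice=ratio(2 * tp, fp + fn + 2 * tp),
        ioup=ratio(tp, fp + fn + tp),
        recall=ratio(tp, tp + fn),
        acc=ratio(tp + tn, c.total),
        tnr=ratio(tn, fp + tn),
    )


def combined_loss(probability: Tensor, gt: np.ndarray, smooth: float = 1e-6) -> Tensor:
    """Binary cross-entropy plus (1 - soft Dice), weighted 1:1; differentiable."""
    gt = np.asarray(gt, dtype=float)
    if probability.shape != gt.shape:
        raise ShapeError(f"shape mismatch: {probability.shape} vs {gt.shape}")
    p = probability.clip(1e-7, 1 - 1e-7)
    g = Tensor(gt)
    bce = -(g * p.log() + (1.0 - g) * (1.0 - p).log()).mean()
    inter = (p * g).sum()
    soft_dice = (2.0 * inter + smooth) / (p.sum() + g.sum() + smooth)
    return bce + (1.0 - soft_dice)


@dataclass
class SeedSummary:
    per_seed_values: list[float]
    mean: float
    spread: float  # sample standard deviation

    def as_dict(self) -> dict:
        return {
            "per_seed": list(self.per_seed_values),
            "mean": self.mean,
            "spread": self.spread,
        }


def seed_aggregate(values: list[float]) -> SeedSummary:
    """Mean and sample standard deviation over per-seed metric values."""
    values = [float(v) for v in values]
    if len(values) < 2:
        raise ValueError("seed aggregation requires at least 2 values")
    arr = np.asarray(values)
    return SeedSummary(
        per_seed_values=values,
        mean=float(arr.mean()),
        spread=float(arr.std(ddof=1)),
    )


def welch_t_test(a: list[float], b: list[float]) -> float:
    """Two-sided Welch unequal-variance t-test; p=1 for degenerate equal groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)
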