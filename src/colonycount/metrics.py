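"""Threshold segmentation of probability maps and evaluation statistics.

Probability maps are arrays in [0, 1].  Binarization is strict
(``p > t``): a pixel exactly at the threshold is background.  The
segmentation F-score used throughout is the weighted form

    F = (1 + b2) * P * R / (b2 * P + R)

with ``b2 = 0.3`` by default, i.e. an F-beta score with beta^2 = 0.3 that
weights precision above recall; ``b2 = 1`` recovers the plain F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PixelConfusion",
    "SweepResult",
    "threshold_mask",
    "precision_recall",
    "f_score",
    "mae",
    "threshold_sweep",
]

#: Sweep grid: 0.1 .. 0.9 in steps of 0.1, plus 0.95 and 0.99.
DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(1, 10)) + (0.95, 0.99)


@dataclass(frozen=True)
class PixelConfusion:
    """Pixel-level confusion counts for one (prediction, ground truth) pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_masks(cls, pred: np.ndarray, gt: np.ndarray) -> "PixelConfusion":
        pred = np.asarray(pred, dtype=bool)
        gt = np.asarray(gt, dtype=bool)
        if pred.shape != gt.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
        tp = int(np.count_nonzero(pred & gt))
        fp = int(np.count_nonzero(pred & ~gt))
        fn = int(np.count_nonzero(~pred & gt))
        tn = int(np.count_nonzero(~pred & ~gt))
        return cls(tp, fp, fn, tn)


def threshold_mask(p: np.ndarray, t: float) -> np.ndarray:
    """Binarize a probability map: foreground where ``p`` strictly exceeds ``t``."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    return np.asarray(p) > t


def precision_recall(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """Pixel precision TP/(TP+FP) and recall TP/(TP+FN).

    Empty-denominator conventions: with no predicted foreground, precision
    is 1 when the ground truth is also empty (nothing falsely claimed) and
    0 otherwise; with no true foreground, recall is 1.
    """
    c = PixelConfusion.from_masks(pred, gt)
    if c.tp + c.fp == 0:
        precision = 1.0 if c.fn == 0 else 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    recall = 1.0 if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn)
    return precision, recall


def f_score(precision: float, recall: float, beta2: float = 0.3) -> float:
    """Weighted F-score (1+b2)PR / (b2 P + R); 0 when P = R = 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta2 * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + beta2) * precision * recall / denom


def mae(p: np.ndarray, gt: np.ndarray) -> float:
    """Mean absolute per-pixel difference between ``p`` and a binary truth."""
    p = np.asarray(p, dtype=np.float64)
    gt = np.asarray(gt)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {gt.shape}")
    vals = np.unique(gt)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("ground truth must be binary")
    return float(np.abs(p - gt.astype(np.float64)).mean())


@dataclass
class SweepResult:
    """Per-threshold, per-image segmentation statistics.

    ``mae``, ``precision`` and ``recall`` have shape
    (n_thresholds, n_images).  The MAE entries compare the *binarized*
    mask at each threshold against the ground truth, so they vary with
    the threshold.
    """

    thresholds: tuple[float, ...]
    mae: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    image_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or not ((t > 0) & (t < 1)).all() or not (np.diff(t) > 0).all():
            raise ValueError("thresholds must be strictly increasing in (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        ids = self.image_ids or [str(i) for i in range(self.mae.shape[1])]
        rows = []
        for i, t in enumerate(self.thresholds):
            for j, img in enumerate(ids):
                rows.append(
                    {
                        "threshold": t,
                        "image": img,
                        "mae": self.mae[i, j],
                        "precision": self.precision[i, j],
                        "recall": self.recall[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Quartiles and 1.5 IQR whiskers per threshold, per metric."""
        rows = []
        for name, arr in (
            ("mae", self.mae),
            ("precision", self.precision),
            ("recall", self.recall),
        ):
            for i, t in enumerate(self.thresholds):
                q1, med, q3 = np.percentile(arr[i], [25, 50, 75])
                iqr = q3 - q1
                vals = arr[i]
                lo = vals[vals >= q1 - 1.5 * iqr].min()
                hi = vals[vals <= q3 + 1.5 * iqr].max()
                rows.append(
                    {
                        "metric": name,
                        "threshold": t,
                        "q1": q1,
                        "median": med,
                        "q3": q3,
                        "whisker_lo": lo,
                        "whisker_hi": hi,
                    }
                )
        return pd.DataFrame(rows)


def threshold_sweep(
    maps: list[np.ndarray],
    gts: list[np.ndarray],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    image_ids: list[str] | None = None,
) -> SweepResult:
    """Evaluate binarization at every threshold over an image set."""
    if len(maps) == 0 or len(maps) != len(gts):
        raise ValueError("need at least one (map, ground truth) pair")
    n_t, n_i = len(thresholds), len(maps)
    out_mae = np.zeros((n_t, n_i))
    out_p = np.zeros((n_t, n_i))
    out_r = np.zeros((n_t, n_i))
    for j, (pm, gt) in enumerate(zip(maps, gts)):
        for i, t in enumerate(thresholds):
            mask = threshold_mask(pm, t)
            out_p[i, j], out_r[i, j] = precision_recall(mask, gt)
            out_mae[i, j] = mae(mask.astype(np.float64), gt)
    return SweepResult(
        tuple(thresholds), out_mae, out_p, out_r, image_ids or []
    )
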