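"""End-to-end plate counting and count-accuracy evaluation.

The count-accuracy metric is *recovery*: for a ground-truth class with
``n_true > 0`` colonies in total,

    recovery = 1 - |n_true - n_pred| / n_true,

while for the empty class (no colonies present) recovery is the
true-negative rate TP / (TP + FN) of a binary "is empty" classification.
Per-class recall and precision over crop classifications are the
column- and row-normalized diagonals of a 10 x 10 confusion matrix whose
rows index the predicted class and columns the ground-truth class.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import label_components, spatially_normalize, standardize_crop
from .counter import predict_counts
from .errors import StageError
from .metrics import threshold_mask
from .preprocess import preprocess_image
from .roi import extract_roi
from .segmenter import predict_probability_map

logger = logging.getLogger(__name__)

__all__ = [
    "CountConfusion",
    "PlateReport",
    "PipelineConfig",
    "recovery",
    "recovery_class0",
    "confusion_report",
    "aggregate_recovery",
    "count_plate",
]

N_CLASSES = 10


def recovery(n_true: int, n_pred: int) -> float:
    """1 - |n_true - n_pred| / n_true for a non-empty ground truth."""
    if n_true <= 0:
        raise ValueError(
            "recovery with the n_true > 0 formula needs a positive true count; "
            "use recovery_class0 for the empty class"
        )
    return 1.0 - abs(n_true - n_pred) / n_true


def recovery_class0(tp: int, fn: int) -> float:
    """Empty-class recovery: the true-negative rate TP / (TP + FN)."""
    if tp < 0 or fn < 0 or tp + fn == 0:
        raise ValueError("need non-negative counts with TP + FN > 0")
    return tp / (tp + fn)


@dataclass
class CountConfusion:
    """Confusion matrix (rows = predicted, cols = truth) with per-class stats."""

    matrix: np.ndarray
    recall: np.ndarray = field(init=False)
    precision: np.ndarray = field(init=False)
    recovery: np.ndarray = field(init=False)

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.shape != (N_CLASSES, N_CLASSES) or (m < 0).any():
            raise ValueError("matrix must be 10x10 with non-negative counts")
        if not np.issubdtype(m.dtype, np.integer):
            if not np.equal(np.mod(m, 1), 0).all():
                raise ValueError("matrix entries must be integer counts")
            m = m.astype(int)
        self.matrix = m
        col = m.sum(axis=0)
        row = m.sum(axis=1)
        diag = np.diag(m)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.recall = np.where(col > 0, diag / np.maximum(col, 1), np.nan)
            self.precision = np.where(row > 0, diag / np.maximum(row, 1), np.nan)
        rec = np.full(N_CLASSES, np.nan)
        if col[0] > 0:
            rec[0] = recovery_class0(int(m[0, 0]), int(col[0] - m[0, 0]))
        classes = np.arange(N_CLASSES)
        for c in range(1, N_CLASSES):
            if col[c] == 0:
                continue
            n_true = c * int(col[c])
            n_pred = int((classes * m[:, c]).sum())
            rec[c] = recovery(n_true, n_pred)
        self.recovery = rec

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix,
            index=[f"pred_{i}" for i in range(N_CLASSES)],
            columns=[f"true_{i}" for i in range(N_CLASSES)],
        )
        for name, vals in (
            ("recall", self.recall),
            ("precision", self.precision),
            ("recovery", self.recovery),
        ):
            df.loc[name] = vals
        return df


def confusion_report(records=None, matrix=None) -> CountConfusion:
    """Build a :class:`CountConfusion` from (true, pred) pairs or a matrix.

    ``records`` is an iterable of ``(true_label, predicted_label)`` with
    labels in 0..9; alternatively pass a prebuilt 10 x 10 ``matrix``
    (rows = predicted class, columns = ground truth).
    """
    if (records is None) == (matrix is None):
        raise ValueError("pass exactly one of records / matrix")
    if matrix is None:
        matrix = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        for true, pred in records:
            true, pred = int(true), int(pred)
            if not (0 <= true < N_CLASSES and 0 <= pred < N_CLASSES):
                raise ValueError(f"labels must lie in 0..9, got {(true, pred)}")
            matrix[pred, true] += 1
    return CountConfusion(matrix=np.asarray(matrix))


def aggregate_recovery(conf: CountConfusion, method: str = "colony_total") -> float:
    """Aggregate recovery over classes.

    ``colony_total`` compares total predicted vs total true colonies
    across all components; ``class_mean`` averages the per-class
    recoveries (ignoring absent classes).  Both are reported because the
    two conventions answer different questions (total biomass recovered
    vs per-difficulty-level accuracy).
    """
    m = conf.matrix
    classes = np.arange(N_CLASSES)
    if method == "colony_total":
        n_true = int((classes * m.sum(axis=0)).sum())
        n_pred_total = int((classes[:, None] * m).sum())
        if n_true == 0:
            raise ValueError("no colonies in the ground truth")
        return recovery(n_true, n_pred_total)
    if method == "class_mean":
        vals = conf.recovery[~np.isnan(conf.recovery)]
        return float(vals.mean())
    raise ValueError(f"unknown aggregation {method!r}")


@dataclass
class PipelineConfig:
    edge_threshold: float = 0.1
    colony_threshold: float = 0.9
    min_area: int = 9
    crop_margin: int = 4


@dataclass
class PlateReport:
    """Per-component predictions for one plate."""

    component_counts: list[int]
    bboxes: list[tuple[int, int, int, int]]
    total: int
    timings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.total != sum(self.component_counts):
            raise ValueError("total must equal the sum of component predictions")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component_id": range(len(self.component_counts)),
                "r0": [b[0] for b in self.bboxes],
                "r1": [b[1] for b in self.bboxes],
                "c0": [b[2] for b in self.bboxes],
                "c1": [b[3] for b in self.bboxes],
                "count": self.component_counts,
            }
        )

    def overlay(self, image: np.ndarray) -> np.ndarray:
        """8-bit copy of ``image`` with white boxes around each component."""
        img = np.asarray(image)
        if img.dtype != np.uint8:
            img = (np.clip(img, 0, 1) * 255).astype(np.uint8)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img.copy()
        for r0, r1, c0, c1 in self.bboxes:
            r0, c0 = max(r0 - 1, 0), max(c0 - 1, 0)
            r1 = min(r1 + 1, img.shape[0])
            c1 = min(c1 + 1, img.shape[1])
            img[r0, c0:c1] = 255
            img[r1 - 1, c0:c1] = 255
            img[r0:r1, c0] = 255
            img[r0:r1, c1 - 1] = 255
        return img


def count_plate(
    image: np.ndarray,
    edge_model,
    colony_model,
    counter_model,
    config: PipelineConfig | None = None,
) -> PlateReport:
    """Run the full pipeline on one raw plate image.

    Stages: intensity-corrected preprocessing -> dish-edge probability
    map -> ROI extraction (threshold ``edge_threshold``) -> colony
    probability map on the ROI image -> threshold ``colony_threshold``
    -> connected components -> spatial normalization -> per-crop count
    prediction.  Any stage failure raises :class:`StageError` naming the
    stage; no partial result is returned.
    """
    cfg = config or PipelineConfig()
    timings = {}

    t0 = time.perf_counter()
    unit, _field, _dish, _medium = preprocess_image(image)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        edge_map = predict_probability_map(edge_model, unit)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("edge_segmentation", str(exc)) from exc
    roi_res = extract_roi(unit, edge_map, t=cfg.edge_threshold)
    timings["roi"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        colony_map = predict_probability_map(colony_model, roi_res.roi_image)
    except Exception as exc:  # noqa: BLE001
        raise StageError("colony_segmentation", str(exc)) from exc
    colony_mask = threshold_mask(colony_map, cfg.colony_threshold) & roi_res.roi_mask
    timings["colony_segmentation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comps = label_components(colony_mask, min_area=cfg.min_area)
    # crops are cut from the corrected image restricted to the dish interior,
    # so near-rim components do not drag bright annulus pixels into the
    # counter's input
    crop_base = unit * roi_res.roi_mask[:, :, None]
    crops = []
    for comp in comps:
        rotated = spatially_normalize(comp, crop_base, margin=cfg.crop_margin)
        comp.crop = standardize_crop(rotated.astype(np.float32))
        crops.append(comp.crop)
    timings["components"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if crops:
        try:
            counts = predict_counts(counter_model, crops).tolist()
        except Exception as exc:  # noqa: BLE001
            raise StageError("counter", str(exc)) from exc
    else:
        counts = []
    timings["counter"] = time.perf_counter() - t0
    logger.info("plate counted: %d components, total %d", len(counts), sum(counts))

    return PlateReport(
        component_counts=[int(c) for c in counts],
        bboxes=[c.bbox for c in comps],
        total=int(sum(counts)),
        timings=timings,
    )
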