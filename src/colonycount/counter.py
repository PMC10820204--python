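"""Per-component colony count classifier (10 classes, 0 to "9 or more").

A residual network maps a standardized 128 x 128 crop to one of ten
count classes; components with nine or more colonies share class 9.
Class imbalance (isolated colonies dominate real plates) is handled by
weighting each class's loss term with

    w_i = max_j(n_j) / n_i

so the most frequent class has weight exactly 1.  The default loss is
binary cross-entropy on logits over one-hot targets with the class
weight applied to each sample's positive term; plain softmax
cross-entropy is available as a config option.

``small-resnet`` (three residual stages, ~0.1M parameters) is the
desk-scale default; ``resnet50-style`` mirrors the 50-layer bottleneck
topology.  Backbones live in a registry so alternates can be swapped in.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np

from ._nn.autograd import (
    Tensor,
    add,
    bce_with_logits,
    global_avg_pool,
    maxpool2d,
    relu,
    softmax_cross_entropy,
)
from ._nn.layers import BatchNorm2d, Conv2d, ConvBnRelu, Linear, Module
from ._nn.optim import Adam
from .components import CROP_SIZE

logger = logging.getLogger(__name__)

__all__ = [
    "CounterConfig",
    "class_weights",
    "build_counter",
    "train_counter",
    "predict_count",
    "predict_counts",
    "COUNTER_BACKBONES",
    "save_counter",
    "load_counter",
]

N_CLASSES = 10


@dataclass
class CounterConfig:
    """Counter training configuration (Adam, lr 1e-4, default betas)."""

    backbone: str = "small-resnet"
    lr: float = 1e-4
    loss: str = "bce"  # "bce" (one-hot, weighted positives) or "ce"
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    val_fraction: float = 0.2
    class_weights: np.ndarray | None = None  # None -> Eq-style weights from data

    def __post_init__(self):
        if self.backbone not in COUNTER_BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; "
                f"registered: {sorted(COUNTER_BACKBONES)}"
            )
        if self.loss not in ("bce", "ce"):
            raise ValueError("loss must be 'bce' or 'ce'")
        if self.class_weights is not None:
            self.class_weights = np.asarray(self.class_weights, dtype=np.float64)
            if self.class_weights.shape != (N_CLASSES,) or (
                self.class_weights <= 0
            ).any():
                raise ValueError("class_weights must be 10 positive values")


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency class weights w_i = max(n) / n_i.

    The most frequent class gets weight exactly 1; classes absent from
    the data get the maximum weight observed among present classes
    (logged), so they neither dominate nor vanish if they appear later.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} counts, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all class counts are zero")
    present = counts > 0
    w = np.ones(N_CLASSES)
    w[present] = counts.max() / counts[present]
    if (~present).any():
        w[~present] = w[present].max()
        logger.info(
            "classes %s have no samples; assigned weight %.3g",
            np.nonzero(~present)[0].tolist(), w[present].max(),
        )
    return w


class ResidualBlock(Module):
    """conv-bn-relu -> conv-bn, plus a (projected) skip, then relu."""

    def __init__(self, c_in, c_out, stride=1, rng=None):
        super().__init__()
        self.conv1 = ConvBnRelu(c_in, c_out, stride=stride, rng=rng)
        self.conv2 = Conv2d(c_out, c_out, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride=stride, padding=0,
                               bias=False, rng=rng)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None

    def __call__(self, x):
        out = self.bn2(self.conv2(self.conv1(x)))
        skip = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return relu(add(out, skip))


class BottleneckBlock(Module):
    """1x1 reduce -> 3x3 -> 1x1 expand (x4), with projected skip."""

    expansion = 4

    def __init__(self, c_in, width, stride=1, rng=None):
        super().__init__()
        c_out = width * self.expansion
        self.c1 = Conv2d(c_in, width, 1, padding=0, bias=False, rng=rng)
        self.b1 = BatchNorm2d(width)
        self.c2 = Conv2d(width, width, 3, stride=stride, bias=False, rng=rng)
        self.b2 = BatchNorm2d(width)
        self.c3 = Conv2d(width, c_out, 1, padding=0, bias=False, rng=rng)
        self.b3 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride=stride, padding=0,
                               bias=False, rng=rng)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None

    def __call__(self, x):
        h = relu(self.b1(self.c1(x)))
        h = relu(self.b2(self.c2(h)))
        h = self.b3(self.c3(h))
        skip = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return relu(add(h, skip))


class CounterNet(Module):
    def __init__(self, blocks, head_features, stem, rng):
        super().__init__()
        self.stem = stem
        self.blocks = blocks
        self.fc = Linear(head_features, N_CLASSES, rng=rng)

    def forward(self, x: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(x, dtype=np.float32))
        for layer in self.stem:
            t = layer(t) if isinstance(layer, Module) else layer(t)
        for blk in self.blocks:
            t = blk(t)
        return self.fc(global_avg_pool(t))

    def __call__(self, x):
        return self.forward(x)


def _build_small_resnet(seed: int) -> CounterNet:
    rng = np.random.default_rng(seed)
    stem = [ConvBnRelu(3, 16, stride=2, rng=rng), lambda t: maxpool2d(t, 2)]
    blocks = [
        ResidualBlock(16, 16, rng=rng),
        ResidualBlock(16, 32, stride=2, rng=rng),
        ResidualBlock(32, 64, stride=2, rng=rng),
    ]
    return CounterNet(blocks, 64, stem, rng)


def _build_resnet50_style(seed: int) -> CounterNet:
    rng = np.random.default_rng(seed)
    stem = [
        Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng),
        BatchNorm2d(64),
        relu,
        lambda t: maxpool2d(t, 2),
    ]
    blocks = []
    c_in = 64
    for width, n_blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
        for b in range(n_blocks):
            blocks.append(
                BottleneckBlock(c_in, width, stride=stride if b == 0 else 1, rng=rng)
            )
            c_in = width * BottleneckBlock.expansion
    return CounterNet(blocks, c_in, stem, rng)


COUNTER_BACKBONES = {
    "small-resnet": _build_small_resnet,
    "resnet50-style": _build_resnet50_style,
}


def build_counter(cfg: CounterConfig) -> CounterNet:
    model = COUNTER_BACKBONES[cfg.backbone](cfg.seed)
    model.backbone = cfg.backbone
    return model


def _as_crop_batch(crops) -> np.ndarray:
    """list of (128, 128[, 3]) crops -> (N, 3, 128, 128) float32 in [0, 1]."""
    out = np.empty((len(crops), 3, CROP_SIZE, CROP_SIZE), dtype=np.float32)
    for i, crop in enumerate(crops):
        crop = np.asarray(crop, dtype=np.float32)
        if crop.shape[:2] != (CROP_SIZE, CROP_SIZE):
            raise ValueError(
                f"crop {i} has shape {crop.shape[:2]}, expected "
                f"({CROP_SIZE}, {CROP_SIZE}); run standardize_crop first"
            )
        if crop.ndim == 2:
            crop = np.stack([crop] * 3, axis=-1)
        out[i] = crop.transpose(2, 0, 1)
    return out


def train_counter(dataset, cfg: CounterConfig, val_dataset=None):
    """Train on (crop, label) pairs; returns ``(model, history)``.

    Crops must be standardized 128 x 128 with values in [0, 1]; labels in
    0..9.  Per-epoch validation accuracy is recorded and the
    best-accuracy parameters are restored before returning.
    """
    labels_all = np.array([int(lab) for _, lab in dataset])
    if labels_all.min() < 0 or labels_all.max() >= N_CLASSES:
        raise ValueError("labels must lie in 0..9")
    rng = np.random.default_rng(cfg.seed)
    if val_dataset is None:
        idx = rng.permutation(len(dataset))
        n_val = max(1, int(round(cfg.val_fraction * len(dataset))))
        val_dataset = [dataset[i] for i in idx[:n_val]]
        dataset = [dataset[i] for i in idx[n_val:]]

    x_train = _as_crop_batch([c for c, _ in dataset])
    y_train = np.array([int(lab) for _, lab in dataset])
    x_val = _as_crop_batch([c for c, _ in val_dataset])
    y_val = np.array([int(lab) for _, lab in val_dataset])

    if cfg.class_weights is not None:
        w = cfg.class_weights
    else:
        counts = np.bincount(y_train, minlength=N_CLASSES)
        w = class_weights(counts)

    model = build_counter(cfg)
    opt = Adam(model.parameters(), lr=cfg.lr)
    n = len(y_train)
    history = []
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = model.forward(xb)
            if cfg.loss == "bce":
                onehot = np.eye(N_CLASSES, dtype=np.float32)[yb]
                loss = bce_with_logits(logits, onehot, pos_weight=w[None, :])
            else:
                loss = softmax_cross_entropy(logits, yb, class_weights=w)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        model.eval()
        preds = predict_counts(model, x_val, raw_batch=True)
        acc = float((preds == y_val).mean())
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_accuracy": acc}
        )
        logger.info("counter epoch %d: loss %.4f, val acc %.4f", epoch,
                    history[-1]["train_loss"], acc)
        if acc > best_acc:
            best_acc = acc
            best_state = model.copy_state()
    if best_state is not None:
        model.load_state(best_state)
    model.eval()
    return model, history


def predict_counts(model, crops, batch_size: int = 64, raw_batch: bool = False):
    """Vectorized count prediction for many crops."""
    x = crops if raw_batch else _as_crop_batch(crops)
    model.eval()
    preds = []
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start : start + batch_size]).data
        preds.append(np.argmax(logits, axis=1))  # argmax: lowest index on ties
    return np.concatenate(preds)


def predict_count(model, crop) -> int:
    """Predicted colony count for one standardized crop (9 = nine or more)."""
    return int(predict_counts(model, [crop])[0])


def save_counter(model: CounterNet, path, cfg: CounterConfig | None = None):
    meta = {
        "kind": "counter",
        "backbone": getattr(model, "backbone", "small-resnet"),
        "config": dataclasses.asdict(cfg) if cfg else {},
    }
    if meta["config"].get("class_weights") is not None:
        meta["config"]["class_weights"] = list(
            np.asarray(meta["config"]["class_weights"], dtype=float)
        )
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.named_state())


def load_counter(path) -> CounterNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta.get("kind") != "counter":
            raise ValueError(f"{path} is not a counter checkpoint")
        model = COUNTER_BACKBONES[meta["backbone"]](0)
        model.backbone = meta["backbone"]
        state = {k: data[k] for k in data.files if k != "__meta__"}
        model.load_state(state)
    model.eval()
    return model
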