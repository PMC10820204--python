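"""Salient-region segmentation network built from residual U-blocks (RSU).

The model is an encoder-decoder of RSU blocks: each RSU is itself a
small U-Net (conv/pool encoder, conv/upsample decoder, residual
connection from its input convolution), and the blocks are stacked in a
top-down pyramid with deep supervision — every decoder stage and the
bottom stage emit a side probability map, and a 1x1 fusion convolution
combines them into the final output.  Two instances are trained: a
dish-edge model (8:1 foreground weighting, no flips) and a colony-region
model (horizontal flip augmentation at rate 0.5).

The ``small`` scale (three stages, narrow channels, 64 px inputs) is the
desk-scale configuration used by the tests; ``full`` mirrors the
published six-stage topology.  Inputs are RGB in [0, 1] with no mean/std
standardization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from ._nn.autograd import (
    Tensor,
    add,
    bce_with_logits,
    concat,
    maxpool2d,
    sigmoid,
    upsample_nearest,
)
from ._nn.layers import Conv2d, ConvBnRelu, Module
from ._nn.optim import AdamW, cosine_lr
from .metrics import f_score, mae, precision_recall, threshold_mask

logger = logging.getLogger(__name__)

__all__ = [
    "SegmenterConfig",
    "TrainConfig",
    "Segmenter",
    "build_segmenter",
    "weighted_bce_loss",
    "train_segmenter",
    "predict_probability_map",
    "save_checkpoint",
    "load_checkpoint",
]

_SCALE_PRESETS = {
    "small": dict(stage_depths=(4, 3, 2), base_channels=16, input_size=(64, 64),
                  dilated_tail=0),
    "full": dict(stage_depths=(7, 6, 5, 4, 4, 4), base_channels=64,
                 input_size=(320, 320), dilated_tail=2),
}


@dataclass
class SegmenterConfig:
    """Architecture hyperparameters.

    ``stage_depths[i]`` is the RSU height of encoder stage i (the last
    entry is the bottom stage); the decoder mirrors the encoder.
    ``dilated_tail`` trailing stages use dilated convolutions instead of
    internal pooling (keeping resolution at depth).  Any field left None
    is filled from the ``scale`` preset.
    """

    scale: str = "small"
    stage_depths: tuple[int, ...] | None = None
    base_channels: int | None = None
    input_size: tuple[int, int] | None = None
    dilated_tail: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scale not in _SCALE_PRESETS:
            raise ValueError(f"unknown scale {self.scale!r}")
        preset = _SCALE_PRESETS[self.scale]
        for key, val in preset.items():
            if getattr(self, key) is None:
                setattr(self, key, val)
        self.stage_depths = tuple(int(d) for d in self.stage_depths)
        self.input_size = tuple(int(s) for s in self.input_size)
        if any(d < 1 for d in self.stage_depths):
            raise ValueError("stage depths must be >= 1")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")

    @property
    def n_side_outputs(self) -> int:
        return len(self.stage_depths)

    def required_divisor(self) -> int:
        """Spatial divisibility the topology requires of the input."""
        div = 1
        n = len(self.stage_depths)
        for i, depth in enumerate(self.stage_depths):
            internal = 0 if i >= n - self.dilated_tail else max(depth - 2, 0)
            div = max(div, 2 ** (i + internal))
        return div


@dataclass
class TrainConfig:
    """Optimization regime for either segmenter.

    Defaults follow the training recipe for the dish-edge model: AdamW
    (lr 1e-3, betas (0.9, 0.999), eps 1e-8), weight decay 1e-4, cosine
    learning-rate decay, batch size 1, BCE-with-logits summed over side
    and fused outputs with an 8:1 foreground weight (the rim covers
    about 1/8 of the background area).  The colony model uses
    ``fg_weight=1`` and ``flip_rate=0.5``.
    """

    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 1e-4
    batch_size: int = 1
    fg_weight: float = 8.0
    flip_rate: float = 0.0
    epochs: int = 20
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ValueError("flip_rate must lie in [0, 1]")


class RSU(Module):
    """Residual U-block of a given height.

    height L encodes L-1 conv stages (with pooling between, except in
    dilated mode where dilation doubles instead) plus a dilated bottom
    conv; the decoder mirrors with skip concatenations; the block input
    convolution provides the residual term.
    """

    def __init__(self, height, c_in, c_mid, c_out, dilated=False, rng=None):
        super().__init__()
        self.height = height
        self.dilated = dilated
        self.conv_in = ConvBnRelu(c_in, c_out, rng=rng)
        self.enc = []
        for i in range(height - 1):
            cin = c_out if i == 0 else c_mid
            dil = 2**i if dilated else 1
            self.enc.append(ConvBnRelu(cin, c_mid, dilation=dil, rng=rng))
        bottom_dil = 2 ** (height - 1) if dilated else 2
        self.bottom = ConvBnRelu(c_mid, c_mid, dilation=bottom_dil, rng=rng)
        self.dec = []
        for i in range(height - 1):
            cout = c_out if i == height - 2 else c_mid
            dil = 2 ** (height - 2 - i) if dilated else 1
            self.dec.append(ConvBnRelu(2 * c_mid, cout, dilation=dil, rng=rng))

    def __call__(self, x: Tensor) -> Tensor:
        hx = self.conv_in(x)
        skips = []
        h = hx
        for i, enc in enumerate(self.enc):
            if i > 0 and not self.dilated:
                h = maxpool2d(h, 2)
            h = enc(h)
            skips.append(h)
        b = self.bottom(h)
        d = b
        for i, dec in enumerate(self.dec):
            skip = skips[-(i + 1)]
            if d.shape[2:] != skip.shape[2:]:
                d = upsample_nearest(d, skip.shape[2:])
            d = dec(concat([d, skip], axis=1))
        return add(d, hx)


class Segmenter(Module):
    """RSU encoder-decoder with deep supervision and a fused output."""

    def __init__(self, cfg: SegmenterConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        depths = cfg.stage_depths
        n = len(depths)
        outs = [cfg.base_channels * 2 ** min(i, 3) for i in range(n)]
        mids = [max(4, o // 2) for o in outs]
        self.encoders = []
        c_prev = 3
        for i in range(n):
            dilated = i >= n - cfg.dilated_tail
            self.encoders.append(
                RSU(depths[i], c_prev, mids[i], outs[i], dilated=dilated, rng=rng)
            )
            c_prev = outs[i]
        self.decoders = []
        for i in range(n - 2, -1, -1):
            dilated = i >= n - cfg.dilated_tail
            c_in = outs[i] + outs[i + 1]
            self.decoders.append(
                RSU(depths[i], c_in, mids[i], outs[i], dilated=dilated, rng=rng)
            )
        # side heads: one per decoder stage plus the bottom stage
        self.side_heads = [Conv2d(outs[i], 1, 3, rng=rng) for i in range(n - 1)]
        self.side_heads.append(Conv2d(outs[n - 1], 1, 3, rng=rng))
        self.fuse = Conv2d(n, 1, 1, padding=0, rng=rng)

    def _check_input(self, x: np.ndarray):
        h, w = x.shape[2], x.shape[3]
        div = self.cfg.required_divisor()
        if h % div or w % div:
            pad_h = (div - h % div) % div
            pad_w = (div - w % div) % div
            raise ValueError(
                f"input {h}x{w} not divisible by {div}; pad by "
                f"({pad_h}, {pad_w}) pixels"
            )

    def forward(self, x: np.ndarray):
        """x: (N, 3, H, W) in [0, 1]. Returns (fused, [side logits...])."""
        x = np.asarray(x, dtype=np.float32)
        self._check_input(x)
        size = x.shape[2:]
        t = Tensor(x)
        feats = []
        h = t
        for i, enc in enumerate(self.encoders):
            if i > 0:
                h = maxpool2d(h, 2)
            h = enc(h)
            feats.append(h)
        sides = [None] * len(self.encoders)
        sides[-1] = self.side_heads[-1](feats[-1])
        d = feats[-1]
        for j, dec in enumerate(self.decoders):
            i = len(self.encoders) - 2 - j
            up = upsample_nearest(d, feats[i].shape[2:])
            d = dec(concat([up, feats[i]], axis=1))
            sides[i] = self.side_heads[i](d)
        side_logits = [
            s if s.shape[2:] == size else upsample_nearest(s, size) for s in sides
        ]
        fused = self.fuse(concat(side_logits, axis=1))
        return fused, side_logits

    def __call__(self, x):
        return self.forward(x)

    @property
    def input_size(self):
        return self.cfg.input_size


def build_segmenter(cfg: SegmenterConfig) -> Segmenter:
    """Construct a randomly initialized model (deterministic per seed)."""
    return Segmenter(cfg)


def weighted_bce_loss(logits, target: np.ndarray, fg_weight: float = 1.0) -> Tensor:
    """Foreground-weighted BCE on logits, summed over all outputs.

    ``logits`` may be one tensor or a sequence (e.g. ``[fused, *sides]``);
    each term is a mean over pixels, terms are summed with equal weight.
    With ``fg_weight=1`` each term is the standard BCE-with-logits.
    """
    target = np.asarray(target)
    vals = np.unique(target)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("target mask must be binary")
    target = target.astype(np.float32)
    if isinstance(logits, Tensor):
        logits = [logits]
    total = None
    for lg in logits:
        term = bce_with_logits(lg, np.broadcast_to(target, lg.shape), fg_weight)
        total = term if total is None else add(total, term)
    return total


def hflip_pair(x: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mirror an image batch and its mask batch horizontally, together.

    The only augmentation used: a left-right mirror along the last
    (column) axis, applied to image and mask jointly so they stay
    aligned.
    """
    return x[..., ::-1].copy(), m[..., ::-1].copy()


def _as_batch(image: np.ndarray) -> np.ndarray:
    """(H, W[, 3]) float [0, 1] -> (1, 3, H, W) float32."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    return image.transpose(2, 0, 1)[None]


def predict_probability_map(model: Segmenter, image: np.ndarray) -> np.ndarray:
    """Fused foreground probability map for one image.

    Images whose size differs from the model's training geometry are
    resized (bilinear) for inference and the map is resized back, which
    preserves the probability ordering; masks derived from it should use
    nearest resampling.
    """
    x = _as_batch(image)
    h, w = x.shape[2:]
    mh, mw = model.input_size
    if (h, w) != (mh, mw):
        div = model.cfg.required_divisor()
        if mh % div or mw % div:
            raise ValueError("model input_size incompatible with topology")
        small = sktransform.resize(
            x[0].transpose(1, 2, 0), (mh, mw), order=1, anti_aliasing=True,
            preserve_range=True,
        )
        x = small.transpose(2, 0, 1)[None].astype(np.float32)
    model.eval()
    fused, _ = model.forward(x)
    prob = sigmoid(fused.data[0, 0])
    if (h, w) != (mh, mw):
        prob = sktransform.resize(prob, (h, w), order=1, preserve_range=True)
    return np.clip(prob, 0.0, 1.0)


def _evaluate(model: Segmenter, dataset) -> tuple[float, float]:
    """Mean F-score (cutoff 0.5) and raw-map MAE over a validation set."""
    fs, maes = [], []
    for image, mask in dataset:
        prob = predict_probability_map(model, image)
        pred = threshold_mask(prob, 0.5)
        p, r = precision_recall(pred, mask)
        fs.append(f_score(p, r))
        maes.append(mae(prob, mask.astype(int)))
    return float(np.mean(fs)), float(np.mean(maes))


def train_segmenter(
    model: Segmenter,
    dataset,
    tc: TrainConfig,
    val_dataset=None,
):
    """Train on (image, mask) pairs; returns ``(model, history)``.

    ``history`` holds one record per epoch with the training loss and
    validation F-score / MAE.  The parameters kept are those of the
    best epoch — highest F-score, ties broken toward lower MAE — and are
    restored into ``model`` before returning.  If ``val_dataset`` is
    None a fraction of ``dataset`` is split off deterministically.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    for image, mask in dataset:
        if image.shape[:2] != mask.shape:
            raise ValueError("image/mask shapes misaligned")
    rng = np.random.default_rng(tc.seed)
    if val_dataset is None:
        idx = rng.permutation(len(dataset))
        n_val = max(1, int(round(tc.val_fraction * len(dataset))))
        val_dataset = [dataset[i] for i in idx[:n_val]]
        dataset = [dataset[i] for i in idx[n_val:]]
        if not dataset:
            raise ValueError("dataset too small to split a validation set")

    opt = AdamW(model.parameters(), lr=tc.lr, betas=tc.betas, eps=tc.eps,
                weight_decay=tc.weight_decay)
    total_steps = tc.epochs * len(dataset)
    history = []
    best = (-1.0, np.inf)
    best_state = None
    step = 0
    for epoch in range(tc.epochs):
        model.train()
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for i in order:
            image, mask = dataset[i]
            x = _as_batch(image)
            m = np.asarray(mask, dtype=np.float32)[None, None]
            if tc.flip_rate and rng.uniform() < tc.flip_rate:
                x, m = hflip_pair(x, m)
            opt.lr = cosine_lr(tc.lr, step, total_steps)
            fused, sides = model.forward(x)
            loss = weighted_bce_loss([fused, *sides], m, tc.fg_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, step {step}; "
                    "lower the learning rate"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            step += 1
        model.eval()
        val_f, val_mae = _evaluate(model, val_dataset)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / len(dataset),
                "val_f_score": val_f,
                "val_mae": val_mae,
            }
        )
        logger.info(
            "epoch %d: loss %.4f, val F %.4f, val MAE %.5f",
            epoch, history[-1]["train_loss"], val_f, val_mae,
        )
        if (val_f, -val_mae) > best:
            best = (val_f, -val_mae)
            best_state = model.copy_state()
    if best_state is not None:
        model.load_state(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: Segmenter, path, extra: dict | None = None):
    meta = {
        "kind": "segmenter",
        "config": dataclasses.asdict(model.cfg),
        "extra": extra or {},
    }
    state = model.named_state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> Segmenter:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta.get("kind") != "segmenter":
            raise ValueError(f"{path} is not a segmenter checkpoint")
        cfg_d = meta["config"]
        cfg_d["stage_depths"] = tuple(cfg_d["stage_depths"])
        cfg_d["input_size"] = tuple(cfg_d["input_size"])
        cfg = SegmenterConfig(**cfg_d)
        model = Segmenter(cfg)
        state = {k: data[k] for k in data.files if k != "__meta__"}
        model.load_state(state)
    model.eval()
    return model
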