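"""Synthetic backlit agar-plate images with exact ground truth.

The generator emulates transmission-illuminated plate photographs: a
bright circular culture-medium region bounded by a dark annular dish
edge (sized so the annulus covers roughly 1/8 of the background area),
colonies rendered as darker-than-medium blobs with radial intensity
falloff, singly or in adhesive clusters, plus a smooth luminosity
gradient and pixel noise.  Every sample carries pixel-exact masks for
the dish edge and the colony region and a per-component true count, so
the segmentation, component-extraction and counting stages can all be
trained and verified without any external dataset.

Randomness: each sample's generator is derived from
``SeedSequence(master_seed, spawn_key=(stream, index))`` so datasets are
reproducible and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "PlateSample",
    "ColonyBlob",
    "render_colony_cluster",
    "generate_plate",
    "generate_plate_set",
    "sample_crop_labels",
    "generate_crop_dataset",
]


def default_count_distribution() -> np.ndarray:
    """Probability of a *non-empty* component holding k = 1..9 colonies.

    The non-empty class mix is 76.6% single, 9% two, 2.2% three and 1.2%
    more than three (split evenly over 4..9), renormalized to exclude
    the 10.9% empty-crop share which is controlled separately by
    ``empty_crop_rate``.
    """
    raw = np.array([0.766, 0.09, 0.022] + [0.012 / 6] * 6)
    return raw / raw.sum()


@dataclass
class SynthConfig:
    """Parameters of the synthetic plate generator.

    ``dish_radius_frac`` is the outer dish radius as a fraction of
    ``min(H, W)``; ``edge_thickness_frac`` is the annulus thickness as a
    fraction of that radius, defaulting to the value that makes the
    annulus cover ~1/8 of the background of a square image.  Intensity
    amplitudes are on the unit luminosity scale.
    """

    image_size: tuple[int, int] = (256, 256)
    dish_radius_frac: float = 0.44
    edge_thickness_frac: float = 0.095
    n_components: int = 20
    count_distribution: np.ndarray = field(default_factory=default_count_distribution)
    empty_crop_rate: float = 0.109
    colony_radius_range: tuple[float, float] = (3.0, 7.0)
    cluster_overlap_frac: float = 0.45
    background_gradient_amp: float = 0.08
    noise_sigma: float = 0.012
    colony_contrast: float = 0.55
    seed: int = 0

    def __post_init__(self):
        self.count_distribution = np.asarray(self.count_distribution, dtype=float)
        if abs(self.count_distribution.sum() - 1.0) > 1e-9:
            raise ValueError("count_distribution must sum to 1 within 1e-9")
        if (self.count_distribution < 0).any():
            raise ValueError("count_distribution must be non-negative")
        if not (0 < self.dish_radius_frac < 0.5):
            raise ValueError("dish_radius_frac must lie in (0, 0.5)")
        for name in ("edge_thickness_frac", "cluster_overlap_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0.0 <= self.empty_crop_rate < 1.0):
            raise ValueError("empty_crop_rate must lie in [0, 1)")
        lo, hi = self.colony_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("colony_radius_range must be positive and ordered")
        if self.n_components < 0:
            raise ValueError("n_components must be >= 0")

    # geometry helpers -----------------------------------------------------
    @property
    def outer_radius(self) -> float:
        return self.dish_radius_frac * min(self.image_size)

    @property
    def inner_radius(self) -> float:
        return self.outer_radius * (1.0 - self.edge_thickness_frac)


@dataclass
class ColonyBlob:
    """One connected cluster of k overlapping colony disks."""

    disks: list[tuple[float, float, float]]  # (row, col, radius)
    pixels: np.ndarray  # (n, 2) int rows/cols of the rasterized union

    @property
    def k(self) -> int:
        return len(self.disks)


def _rasterize_disks(disks) -> np.ndarray:
    """Lattice points covered by a union of disks (d <= r per disk)."""
    pts = []
    for cy, cx, r in disks:
        r0, r1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        c0, c1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        yy, xx = np.mgrid[r0:r1, c0:c1]
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        pts.append(np.column_stack([yy[inside], xx[inside]]))
    allpts = np.concatenate(pts, axis=0)
    return np.unique(allpts, axis=0)


def render_colony_cluster(
    k: int,
    center: tuple[float, float],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> ColonyBlob:
    """Place ``k`` overlapping disks on a short random walk from ``center``.

    Consecutive disks overlap by ``cluster_overlap_frac`` of their summed
    radii, which guarantees the rasterized union is one 8-connected blob.
    """
    if not 1 <= k <= 12:
        raise ValueError("k must lie in 1..12")
    lo, hi = cfg.colony_radius_range
    disks = []
    cy, cx = float(center[0]), float(center[1])
    r_prev = float(rng.uniform(lo, hi))
    disks.append((cy, cx, r_prev))
    for _ in range(k - 1):
        r = float(rng.uniform(lo, hi))
        step = (r_prev + r) * (1.0 - cfg.cluster_overlap_frac)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        cy += step * np.sin(ang)
        cx += step * np.cos(ang)
        disks.append((cy, cx, r))
        r_prev = r
    return ColonyBlob(disks=disks, pixels=_rasterize_disks(disks))


@dataclass
class PlateSample:
    """A rendered plate with exact ground truth."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    edge_mask: np.ndarray  # bool, dish annulus
    colony_mask: np.ndarray  # bool, union of colony blobs
    components: list[tuple[np.ndarray, int]]  # (pixel array (n,2), true count)
    total_count: int

    def __post_init__(self):
        h, w = self.image.shape[:2]
        if self.edge_mask.shape != (h, w) or self.colony_mask.shape != (h, w):
            raise ValueError("masks must match image shape")
        if self.total_count != sum(k for _, k in self.components):
            raise ValueError("total_count must equal the sum of component counts")


def _luminosity_base(cfg: SynthConfig, rng: np.random.Generator):
    """Background luminosity field and region masks (no colonies yet)."""
    h, w = cfg.image_size
    cy = h / 2.0 + rng.uniform(-0.01, 0.01) * h
    cx = w / 2.0 + rng.uniform(-0.01, 0.01) * w
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - cy, xx - cx)
    r_out, r_in = cfg.outer_radius, cfg.inner_radius
    interior = d < r_in
    edge = (d >= r_in) & (d <= r_out)
    lum = np.full((h, w), 0.45, dtype=np.float64)
    lum[interior] = 0.85
    lum[edge] = 0.10
    ang = rng.uniform(0, 2 * np.pi)
    gx, gy = np.cos(ang), np.sin(ang)
    lum += cfg.background_gradient_amp * (
        (xx - cx) / w * gx + (yy - cy) / h * gy
    )
    return lum, interior, edge, (cy, cx)


def _stamp_colony(lum, blob: ColonyBlob, cfg: SynthConfig):
    """Darken the luminosity field under each disk with radial falloff."""
    h, w = lum.shape
    for cy, cx, r in blob.disks:
        r0 = max(0, int(np.floor(cy - r)))
        r1 = min(h, int(np.ceil(cy + r)) + 1)
        c0 = max(0, int(np.floor(cx - r)))
        c1 = min(w, int(np.ceil(cx + r)) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = d2 <= r * r
        # step edge at the rim plus a radial dome toward the centre
        depth = cfg.colony_contrast * 0.85 * (1.0 - 0.5 * d2 / (r * r))
        patch = lum[r0:r1, c0:c1]
        patch[inside] = np.minimum(patch[inside], (0.85 - depth)[inside])


def _rgb_from_luminosity(lum: np.ndarray) -> np.ndarray:
    tint = np.array([1.0, 0.96, 0.88])
    return np.clip(lum[:, :, None] * tint[None, None, :], 0.0, 1.0).astype(np.float32)


def generate_plate(cfg: SynthConfig, index: int = 0) -> PlateSample:
    """Render one plate; deterministic in ``(cfg.seed, index)``."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0, index)))
    h, w = cfg.image_size
    lum, interior, edge, (cy, cx) = _luminosity_base(cfg, rng)
    r_in = cfg.inner_radius

    colony_mask = np.zeros((h, w), dtype=bool)
    occupied = np.zeros((h, w), dtype=bool)  # colonies + 2 px separation halo
    components: list[tuple[np.ndarray, int]] = []
    sizes = np.arange(1, len(cfg.count_distribution) + 1)
    placed = 0
    for _ in range(cfg.n_components):
        k = int(rng.choice(sizes, p=cfg.count_distribution))
        ok = False
        for _attempt in range(60):
            rho = r_in * 0.92 * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            center = (cy + rho * np.sin(ang), cx + rho * np.cos(ang))
            blob = render_colony_cluster(k, center, cfg, rng)
            px = blob.pixels
            if (px < 0).any() or (px[:, 0] >= h).any() or (px[:, 1] >= w).any():
                continue
            dpix = np.hypot(px[:, 0] - cy, px[:, 1] - cx)
            if (dpix >= r_in - 2.0).any():
                continue  # must stay strictly inside the dish interior
            # separation check against the halo of previously placed blobs
            if occupied[px[:, 0], px[:, 1]].any():
                continue
            ok = True
            break
        if not ok:
            logger.warning(
                "could not place a %d-colony component after 60 attempts; "
                "placing fewer components",
                k,
            )
            continue
        colony_mask[px[:, 0], px[:, 1]] = True
        rr0, cc0 = np.maximum(px.min(axis=0) - 3, 0)
        rr1, cc1 = np.minimum(px.max(axis=0) + 4, (h, w))
        occupied[rr0:rr1, cc0:cc1] = True
        components.append((px, k))
        _stamp_colony(lum, blob, cfg)
        placed += 1

    lum += rng.normal(0.0, cfg.noise_sigma, size=(h, w))
    lum = np.clip(lum, 0.02, 0.98)
    image = _rgb_from_luminosity(lum)
    return PlateSample(
        image=image,
        edge_mask=edge,
        colony_mask=colony_mask,
        components=components,
        total_count=sum(k for _, k in components),
    )


def generate_plate_set(n: int, cfg: SynthConfig, start_index: int = 0):
    """List of ``n`` plates at consecutive sample indices."""
    return [generate_plate(cfg, index=start_index + i) for i in range(n)]


def _draw_label(rng: np.random.Generator, cfg: SynthConfig) -> int:
    """Crop label: 0 with ``empty_crop_rate``, else k drawn from the mix."""
    if rng.uniform() < cfg.empty_crop_rate:
        return 0
    sizes = np.arange(1, len(cfg.count_distribution) + 1)
    k = int(rng.choice(sizes, p=cfg.count_distribution))
    return min(k, 9)


def sample_crop_labels(n: int, cfg: SynthConfig) -> np.ndarray:
    """The label sequence ``generate_crop_dataset`` would produce, labels only."""
    return np.array(
        [
            _draw_label(
                np.random.default_rng(
                    np.random.SeedSequence(cfg.seed, spawn_key=(1, i))
                ),
                cfg,
            )
            for i in range(n)
        ],
        dtype=int,
    )


def _render_crop(rng: np.random.Generator, cfg: SynthConfig, k: int):
    """A small medium-background canvas holding one k-colony blob (or none)."""
    lo, hi = cfg.colony_radius_range
    if k == 0:
        side = int(np.ceil(hi * 4))
        lum = np.full((side, side), 0.85)
        mask = np.zeros((side, side), dtype=bool)
    else:
        # size the canvas to the worst-case walk extent plus margin
        extent = int(np.ceil(2 * hi + 2 * hi * (1 - cfg.cluster_overlap_frac) * (k - 1)))
        side = extent + 12
        center = (side / 2.0, side / 2.0)
        blob = render_colony_cluster(k, center, cfg, rng)
        px = blob.pixels
        shift = np.array([side // 2, side // 2]) - (
            (px.min(axis=0) + px.max(axis=0)) // 2
        )
        blob = ColonyBlob(
            disks=[(cy + shift[0], cx + shift[1], r) for cy, cx, r in blob.disks],
            pixels=px + shift,
        )
        px = blob.pixels
        if (px < 0).any() or (px >= side).any():  # pragma: no cover - margin guard
            keep = (px >= 0).all(axis=1) & (px < side).all(axis=1)
            px = px[keep]
        lum = np.full((side, side), 0.85)
        _stamp_colony(lum, blob, cfg)
        mask = np.zeros((side, side), dtype=bool)
        mask[px[:, 0], px[:, 1]] = True
    ang = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:side, 0:side]
    lum += cfg.background_gradient_amp * 0.5 * (
        (xx - side / 2) / side * np.cos(ang) + (yy - side / 2) / side * np.sin(ang)
    )
    lum += rng.normal(0.0, cfg.noise_sigma, size=lum.shape)
    lum = np.clip(lum, 0.02, 0.98)
    return _rgb_from_luminosity(lum), mask


def generate_crop_dataset(
    n: int,
    cfg: SynthConfig,
    rotation: str = "normalized",
) -> list[tuple[np.ndarray, int]]:
    """``n`` standardized 128x128 crops with count labels 0-9.

    Crops are rendered on a medium background, converted to the
    intensity-corrected unit scale used by the counting network (the
    same transform the live pipeline applies), masked to the component
    plus a 4 px margin, rotated according to ``rotation`` and
    standardized to 128x128.

    rotation modes: ``"normalized"`` aligns the fitted-ellipse major
    axis vertically (the pipeline default); ``"none"`` leaves crops
    as rendered; ``"random45"`` rotates each crop by 45 degrees in a
    random direction (the degraded treatment used for comparison).
    """
    from .components import label_components, spatially_normalize, standardize_crop
    from .preprocess import correct_intensity, to_unit_image

    if n < 1:
        raise ValueError("n must be >= 1")
    if rotation not in ("normalized", "none", "random45"):
        raise ValueError(f"unknown rotation mode {rotation!r}")

    out = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, i)))
        label = _draw_label(rng, cfg)
        image, mask = _render_crop(rng, cfg, label)
        lum = image.mean(axis=2).astype(np.float64)
        i0 = float(lum[~mask].mean())
        corrected = correct_intensity(image, i0)
        unit = to_unit_image(corrected)
        if label == 0:
            crop = standardize_crop(unit)
        else:
            comps = label_components(mask, min_area=1)
            comp = max(comps, key=lambda c: len(c.pixel_set))
            if rotation == "normalized":
                rotated = spatially_normalize(comp, unit)
            else:
                rotated = spatially_normalize(comp, unit, rotate=False)
                if rotation == "random45":
                    from skimage.transform import rotate as _rot

                    sign = 1.0 if rng.uniform() < 0.5 else -1.0
                    rotated = _rot(rotated, sign * 45.0, resize=True, order=1)
            crop = standardize_crop(rotated.astype(np.float32))
        out.append((crop.astype(np.float32), int(label)))
    return out
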