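"""Connected-component extraction and spatial normalization of colony crops.

A colony component (CC) is one connected region of the binarized colony
mask; it may hold a single colony or several adhered ones.  Before
counting, each component is spatially normalized: an ellipse is fitted
from the second-order central moments of its pixel set and the crop is
rotated about the ellipse centre so the major axis points vertically.
Crops are then standardized to 128 x 128 (pad small crops with zeros,
shrink large ones preserving aspect ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseFit",
    "ColonyComponent",
    "label_components",
    "fit_ellipse",
    "spatially_normalize",
    "standardize_crop",
    "CROP_SIZE",
]

CROP_SIZE = 128

#: skip rotation when minor/major exceeds this (orientation is unstable
#: for near-circular components)
EPS_CIRCULAR = 0.95


@dataclass(frozen=True)
class EllipseFit:
    """Moment ellipse: centre (row, col), axis lengths, orientation.

    ``theta`` is the angle in degrees between the major axis and the
    vertical (row) axis, in (-90, 90].
    """

    center: tuple[float, float]
    major: float
    minor: float
    theta: float


@dataclass
class ColonyComponent:
    """One connected foreground region with geometry and optional crop."""

    id: int
    pixel_set: np.ndarray  # (n, 2) int, 0-based (row, col)
    bbox: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)
    ellipse: EllipseFit | None = None
    crop: np.ndarray | None = None
    label: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def area(self) -> int:
        return len(self.pixel_set)


def label_components(
    mask: np.ndarray,
    connectivity: int = 2,
    min_area: int = 9,
) -> list[ColonyComponent]:
    """Label a binary mask into components sorted by bounding-box origin.

    8-connectivity by default (``connectivity=2``); components smaller
    than ``min_area`` pixels are dropped (threshold speckle) and logged.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=connectivity)
    comps = []
    dropped = 0
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            dropped += 1
            continue
        r0, c0, r1, c1 = region.bbox
        comps.append(
            ColonyComponent(
                id=-1,
                pixel_set=region.coords.astype(int),
                bbox=(r0, r1, c0, c1),
            )
        )
    if dropped:
        logger.info("dropped %d components below min_area=%d", dropped, min_area)
    comps.sort(key=lambda c: (c.bbox[0], c.bbox[2]))
    for i, c in enumerate(comps):
        c.id = i
    return comps


def fit_ellipse(component: ColonyComponent | np.ndarray) -> EllipseFit:
    """Fit the moment ellipse of a pixel set.

    Axis lengths are 4 * sqrt(eigenvalue) of the pixel covariance (the
    full axis of the equal-moment ellipse, up to the discrete-lattice
    approximation).  For degenerate (collinear) pixel sets the minor
    axis is 0 and the orientation follows the line direction.
    """
    pts = component.pixel_set if isinstance(component, ColonyComponent) else component
    pts = np.asarray(pts, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 pixels to fit an ellipse")
    center = pts.mean(axis=0)
    d = pts - center
    cov = d.T @ d / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major_val, minor_val = evals[1], max(evals[0], 0.0)
    vr, vc = evecs[:, 1]  # major-axis direction (d_row, d_col)
    if vr < 0 or (vr == 0 and vc < 0):
        vr, vc = -vr, -vc
    theta = float(np.degrees(np.arctan2(vc, vr)))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    if theta == -90.0:
        theta = 90.0
    ell = EllipseFit(
        center=(float(center[0]), float(center[1])),
        major=float(4.0 * np.sqrt(major_val)),
        minor=float(4.0 * np.sqrt(minor_val)),
        theta=theta,
    )
    if isinstance(component, ColonyComponent):
        component.ellipse = ell
    return ell


def spatially_normalize(
    component: ColonyComponent,
    image: np.ndarray,
    margin: int = 4,
    rotate: bool = True,
    eps_circular: float = EPS_CIRCULAR,
    return_mask: bool = False,
):
    """Cut, mask and rotation-align the crop of one component.

    The crop covers the component bounding box plus ``margin`` pixels;
    pixels outside the component mask dilated by ``margin`` are zeroed
    (neighbouring components are excluded while adhesion-boundary
    texture is preserved).  If the component is clearly elongated
    (minor/major <= ``eps_circular``) the crop is rotated about the
    ellipse centre so the fitted major axis becomes vertical; rotation
    is skipped for near-circular components, whose orientation is not
    meaningful.
    """
    ell = component.ellipse or fit_ellipse(component)
    h, w = image.shape[:2]
    r0, r1, c0, c1 = component.bbox
    r0e, c0e = max(r0 - margin, 0), max(c0 - margin, 0)
    r1e, c1e = min(r1 + margin, h), min(c1 + margin, w)

    local_mask = np.zeros((r1e - r0e, c1e - c0e), dtype=bool)
    local_mask[component.pixel_set[:, 0] - r0e, component.pixel_set[:, 1] - c0e] = True
    keep = ndimage.binary_dilation(local_mask, structure=morphology.disk(margin))
    crop = np.asarray(image, dtype=np.float64)[r0e:r1e, c0e:c1e].copy()
    if crop.ndim == 3:
        crop *= keep[:, :, None]
    else:
        crop *= keep

    do_rotate = rotate and ell.major > 0 and (ell.minor / ell.major) <= eps_circular
    if not do_rotate:
        if return_mask:
            return crop, local_mask
        return crop

    center_local = (ell.center[1] - c0e, ell.center[0] - r0e)  # (col, row)

    def _rotated(angle):
        rc = transform.rotate(crop, -angle, resize=True, center=center_local,
                              order=1, preserve_range=True)
        rm = transform.rotate(local_mask.astype(float), -angle, resize=True,
                              center=center_local, order=1,
                              preserve_range=True) > 0.5
        return rc, rm

    # One-shot rotation by -theta can miss vertical by several degrees on
    # small pixel sets: rasterizing the rotated mask perturbs the moments,
    # and the perturbation is an oscillating function of the angle, so a
    # plain fixed-point iteration need not settle.  Instead evaluate a few
    # candidate angles (fixed-point steps, then a 1-degree refinement grid
    # around the best) and keep the angle whose rasterized residual is
    # smallest; the original is resampled exactly once per candidate.
    def _residual(angle):
        _, rm = _rotated(angle)
        return fit_ellipse(np.argwhere(rm)).theta

    angle = ell.theta
    res = _residual(angle)
    best_angle, best_res = angle, res
    for _ in range(4):
        if abs(best_res) <= 1.0:
            break
        angle = angle + res
        res = _residual(angle)
        if abs(res) < abs(best_res):
            best_angle, best_res = angle, res
    if abs(best_res) > 1.0:
        for delta in (-2.0, -1.0, 1.0, 2.0):
            res = _residual(best_angle + delta)
            if abs(res) < abs(best_res):
                best_angle, best_res = best_angle + delta, res

    rot_crop, rot_mask = _rotated(best_angle)
    if return_mask:
        return rot_crop, rot_mask
    return rot_crop


def standardize_crop(crop: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Standardize a crop to ``size`` x ``size``.

    If both sides fit, the content is centred in a zero canvas.
    Otherwise the long side is scaled down to ``size`` (aspect ratio
    kept, short side rounded to the nearest integer, at least 1) and
    the short side is zero-padded.  Idempotent for already-standard
    crops.
    """
    crop = np.asarray(crop)
    if crop.size == 0:
        raise ValueError("empty crop")
    h, w = crop.shape[:2]
    if max(h, w) > size:
        s = size / max(h, w)
        nh = size if h >= w else max(1, int(np.floor(h * s + 0.5)))
        nw = size if w >= h else max(1, int(np.floor(w * s + 0.5)))
        out_shape = (nh, nw) + crop.shape[2:]
        crop = transform.resize(
            crop.astype(np.float64), out_shape, order=1, anti_aliasing=True,
            preserve_range=True,
        )
        h, w = nh, nw
    canvas_shape = (size, size) + crop.shape[2:]
    canvas = np.zeros(canvas_shape, dtype=np.float32)
    r0 = (size - h) // 2
    c0 = (size - w) // 2
    canvas[r0 : r0 + h, c0 : c0 + w] = crop
    return canvas
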