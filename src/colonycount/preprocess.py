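"""Luminosity-corrected preprocessing of backlit plate images.

The dominant nuisance in transmission-illuminated plate photographs is
the medium itself: batch-to-batch differences in agar composition and
thickness shift the luminosity of the whole field.  The correction
references every pixel against the mean luminosity ``I0`` of the culture
medium region:

    corrected_i = log10(I0) - log10(I_i)

so medium pixels sit near zero, colonies (darker, i.e. lower
transmitted intensity) become positive, and multiplying the raw image by
any constant c > 0 leaves the corrected field unchanged.  ``lg`` is read
as log10; any fixed base only rescales the field and is absorbed when
network inputs are normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, restoration

from .errors import StageError

__all__ = [
    "IntensityField",
    "luminosity",
    "rough_dish_segment",
    "estimate_medium_reference",
    "correct_intensity",
    "to_unit_image",
    "preprocess_image",
]

#: floor on raw intensities so logs stay finite (16-bit quantum)
EPS_INTENSITY = 1.0 / 65535.0

#: fixed display window mapping corrected values onto [0, 1]
UNIT_WINDOW = (-0.2, 1.0)


@dataclass(frozen=True)
class IntensityField:
    """Raw luminosity, medium reference and corrected field for one image."""

    luminosity: np.ndarray
    i0: float
    corrected: np.ndarray

    def __post_init__(self):
        if self.i0 <= 0:
            raise ValueError("I0 must be positive")


def luminosity(image: np.ndarray) -> np.ndarray:
    """Per-pixel luminosity: the mean of the R, G, B channels."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[:, :, :3].mean(axis=2)
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got {image.shape}")


def rough_dish_segment(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Approximate dish and medium masks from a raw backlit image.

    Denoise, threshold the bright transmitted-light disk, take its
    largest connected region as the dish, then exclude a rough
    foreground estimate (colony rims found by gradient-magnitude edge
    detection, plus markedly dark pixels) to leave the culture-medium
    region.  This mask is only used to estimate ``I0``; the trained
    segmenters refine everything downstream.
    """
    lum = luminosity(image)
    if lum.max() <= 0:
        raise StageError("rough_dish_segment", "image is entirely dark")
    scale = lum.max()
    lum_n = lum / scale
    den = restoration.denoise_bilateral(
        lum_n, win_size=5, sigma_color=0.1, sigma_spatial=2.0
    )
    thr = filters.threshold_otsu(den)
    bright = den > thr
    labels, n = ndimage.label(bright)
    if n == 0:
        raise StageError("rough_dish_segment", "no bright dish region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < 0.05 * lum.size:
        raise StageError(
            "rough_dish_segment",
            f"largest bright component covers {sizes[best - 1] / lum.size:.1%} "
            "of the image (< 5%); not a backlit plate",
        )
    dish = ndimage.binary_fill_holes(labels == best)

    # rough foreground: strong edges (colony rims) plus markedly dark pixels.
    # The gradient threshold comes from the whole image so the dish rim sets
    # its scale and in-dish noise stays below it.
    grad = filters.sobel(den)
    gthr = filters.threshold_otsu(grad)
    # ignore the gradient ring bleeding inward from the dish rim itself
    dish_core = ndimage.binary_erosion(dish, structure=morphology.disk(5))
    edges = (grad > max(gthr, 1e-6)) & dish_core
    edges = ndimage.binary_dilation(edges, structure=morphology.disk(3))
    med = np.median(den[dish])
    dark = (den < 0.8 * med) & dish
    dark = ndimage.binary_dilation(dark, structure=morphology.disk(2))
    medium = (
        ndimage.binary_erosion(dish, structure=morphology.disk(2)) & ~edges & ~dark
    )
    if not medium.any():
        raise StageError("rough_dish_segment", "medium region estimate is empty")
    return dish, medium


def estimate_medium_reference(image: np.ndarray, medium_mask: np.ndarray) -> float:
    """Mean luminosity over the medium region (the ``I0`` reference)."""
    mask = np.asarray(medium_mask, dtype=bool)
    if not mask.any():
        raise ValueError("medium mask is empty")
    return float(luminosity(image)[mask].mean())


def correct_intensity(image: np.ndarray, i0: float) -> np.ndarray:
    """Apply the log-ratio correction against the medium reference.

    For a 2-D luminosity field the output is
    ``log10(i0) - log10(max(I, eps))`` directly.  For an RGB image the
    correction is computed on luminosity and each channel is scaled by
    ``corrected / raw`` so hue is preserved while the output luminosity
    equals the corrected field.
    """
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    image = np.asarray(image, dtype=np.float64)
    lum = luminosity(image)
    lum_f = np.maximum(lum, EPS_INTENSITY)
    corrected = np.log10(i0) - np.log10(lum_f)
    if image.ndim == 2:
        return corrected
    ratio = corrected / lum_f
    return image * ratio[:, :, None]


def to_unit_image(corrected: np.ndarray,
                  window: tuple[float, float] = UNIT_WINDOW) -> np.ndarray:
    """Affinely map a corrected field into [0, 1] with a fixed window.

    The window is fixed (not per-image) so the mapping inherits the
    illumination invariance of the correction.  Used both for network
    input and, scaled to 8-bit, for visualization.
    """
    lo, hi = window
    return np.clip((np.asarray(corrected, dtype=np.float64) - lo) / (hi - lo), 0.0, 1.0)


def preprocess_image(image: np.ndarray):
    """Full preprocessing: rough masks, ``I0``, corrected field, unit image.

    Returns ``(unit_image, field, dish_mask, medium_mask)`` where
    ``unit_image`` is the [0, 1] network input.
    """
    dish, medium = rough_dish_segment(image)
    i0 = estimate_medium_reference(image, medium)
    corrected = correct_intensity(image, i0)
    field = IntensityField(luminosity=luminosity(image), i0=i0,
                           corrected=corrected)
    return to_unit_image(corrected), field, dish, medium
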