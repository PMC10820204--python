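"""Petri-dish ROI extraction from the edge model's probability map.

The edge model highlights the annular dish rim.  Binarizing its output
at a low threshold (default 0.1 — lower thresholds yield a more
complete, reliably closed annulus), morphologically closing pixel gaps
and flood-filling from the annulus centroid isolates the dish interior
(culture medium plus colonies), which is the region of interest for the
colony segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import StageError
from .metrics import threshold_mask

__all__ = ["RoiResult", "extract_roi", "DEFAULT_EDGE_THRESHOLD"]

DEFAULT_EDGE_THRESHOLD = 0.1


@dataclass
class RoiResult:
    edge_mask: np.ndarray  # binarized (and closed) annulus
    roi_mask: np.ndarray  # dish interior
    roi_image: np.ndarray  # input with pixels outside annulus+interior zeroed

    def __post_init__(self):
        if (self.edge_mask & self.roi_mask).any():
            raise ValueError("ROI interior must not intersect the annulus")


def extract_roi(
    image: np.ndarray,
    edge_map: np.ndarray,
    t: float = DEFAULT_EDGE_THRESHOLD,
    max_closing_iter: int = 3,
) -> RoiResult:
    """Separate the dish interior enclosed by the thresholded edge annulus.

    The annulus is closed with a 3x3 structuring element, up to
    ``max_closing_iter`` iterations, until the region around its
    centroid no longer floods to the image border.  Raises
    :class:`StageError` if the annulus never closes (the caller may
    lower ``t`` or fall back to the rough dish segmentation).
    """
    edge_map = np.asarray(edge_map, dtype=float)
    annulus = threshold_mask(edge_map, t)
    if not annulus.any():
        raise StageError("extract_roi", f"edge map empty at threshold {t}")
    h, w = annulus.shape
    structure = np.ones((3, 3), dtype=bool)

    for closing_iter in range(max_closing_iter + 1):
        closed = (
            ndimage.binary_closing(annulus, structure=structure,
                                   iterations=closing_iter, border_value=0)
            if closing_iter
            else annulus
        )
        cy, cx = ndimage.center_of_mass(closed)
        seed = (int(round(cy)), int(round(cx)))
        if closed[seed]:
            # centroid landed on the annulus itself; probe nearby interior
            free = np.argwhere(~closed)
            if free.size == 0:
                raise StageError("extract_roi", "annulus covers the whole image")
            d = np.abs(free - np.array(seed)).sum(axis=1)
            seed = tuple(free[np.argmin(d)])
        labels, _ = ndimage.label(~closed)
        interior = labels == labels[seed]
        touches_border = (
            interior[0, :].any()
            or interior[-1, :].any()
            or interior[:, 0].any()
            or interior[:, -1].any()
        )
        if not touches_border:
            roi_image = np.asarray(image, dtype=np.float64).copy()
            outside = ~(interior | closed)
            if roi_image.ndim == 3:
                roi_image[outside] = 0.0
            else:
                roi_image[outside] = 0.0
            return RoiResult(edge_mask=closed, roi_mask=interior, roi_image=roi_image)

    raise StageError(
        "extract_roi",
        f"annulus not closed after {max_closing_iter} closing iterations at "
        f"threshold {t}; lower the threshold or use rough_dish_segment",
    )
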