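"""Morphological lung-field (lobe) segmentation and ROI masking.

The lung fields in a CT slice are dark regions surrounded by a bright body /
background. They are isolated by a fixed six-step morphological recipe:
Otsu binarisation (keeping the dark class), border clearing, connected
component labelling, retention of the two largest components, a small
erosion that detaches vessel-linked structures, and a large closing plus
hole filling that re-attaches wall-adherent nodules. The ROI is then the
element-wise product of the slice with the resulting mask.

The whole chain is deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = ["NoLungFieldError", "segment_lobes", "extract_roi"]


class NoLungFieldError(ValueError):
    """Raised when the morphological chain finds no lung field."""


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 32:
        raise ValueError("image must be 2-D and at least 32x32")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def segment_lobes(
    image: np.ndarray,
    erosion_radius: int = 2,
    closing_radius: int = 10,
    keep_k: int = 2,
) -> np.ndarray:
    """Isolate the lung fields of a CT-like slice as a binary mask.

    Steps, in order: (1) Otsu threshold, keeping the below-threshold (dark)
    class; (2) remove blobs touching the image border; (3) label connected
    components (8-connectivity); (4) keep the ``keep_k`` largest components
    (all of them, with a warning, if fewer exist); (5) erode with a disk of
    ``erosion_radius``; (6) close with a disk of ``closing_radius`` and fill
    holes.

    Returns a uint8 {0,1} mask of the image's shape.  Raises
    :class:`NoLungFieldError` for images in which no dark component
    survives (e.g. a uniform image).
    """
    image = _validate_image(image)
    try:
        thr = threshold_otsu(image)
    except ValueError as exc:  # constant image
        raise NoLungFieldError("no lung field found") from exc
    binary = image < thr

    cleared = segmentation.clear_border(binary)
    labels = measure.label(cleared, connectivity=2)
    if labels.max() == 0:
        raise NoLungFieldError("no lung field found")

    sizes = np.bincount(labels.ravel())[1:]
    if sizes.size < keep_k:
        logger.warning(
            "only %d component(s) found, fewer than keep_k=%d; keeping all",
            sizes.size, keep_k,
        )
        keep = np.arange(1, sizes.size + 1)
    else:
        keep = np.argsort(sizes)[::-1][:keep_k] + 1
    mask = np.isin(labels, keep)

    mask = morphology.erosion(mask, morphology.disk(erosion_radius))
    if not mask.any():
        raise NoLungFieldError("no lung field found")
    mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    return mask.astype(np.uint8)


def extract_roi(image: np.ndarray, lobe_mask: np.ndarray) -> np.ndarray:
    """Apply the lobe mask: pixels outside the mask become exactly 0."""
    image = np.asarray(image, dtype=float)
    lobe_mask = np.asarray(lobe_mask)
    if image.shape != lobe_mask.shape:
        raise ValueError("incompatible mask: shape differs from image")
    return image * (lobe_mask != 0)
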