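"""RGB hill-patch preprocessing: decorrelation stretch, green thresholding,
small-component removal.

The segmentation strategy is deliberately simple: paddy scenes at proximal
range separate well into green leaf tissue versus water/soil background once
inter-channel correlation is removed.  A decorrelation stretch whitens the
channel covariance and rescales each component back to its original standard
deviation, exaggerating hue differences; a single threshold on the green
channel relative to the whole-patch mean then yields a plant mask, and
connected components smaller than an area cutoff (sun glints on the water
surface, floating debris) are discarded.

Coordinate convention used package-wide: arrays are row-major with row 0 at
the top, so "above" always means a smaller row index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdConfig",
    "DegenerateImageWarning",
    "decorrelation_stretch",
    "binarize_green",
    "remove_small_components",
    "crop",
    "load_image",
    "save_mask",
]


class DegenerateImageWarning(UserWarning):
    """Raised (as a warning) when an image is too degenerate to process
    meaningfully, e.g. a constant-colour patch with singular covariance."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Binarization parameters.

    Parameters
    ----------
    k:
        Dimensionless multiplier of the whole-patch mean green value.  A pixel
        is classified as plant when ``green >= k * mean(green)``.  Field use
        sits in [0.9, 1.1]; values outside [0.5, 2.0] are rejected as almost
        certainly a units mistake.
    min_component_area:
        Connected components (8-connectivity) with strictly fewer pixels than
        this survive-threshold are removed from the mask.  The default of 500
        pixels is sized to delete specular water reflections while keeping
        every genuine leaf region.
    """

    k: float = 1.0
    min_component_area: int = 500

    def __post_init__(self) -> None:
        if not (0.5 <= self.k <= 2.0):
            raise ValueError(f"threshold ratio k={self.k} outside [0.5, 2.0]")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0")


def _as_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("empty image")
    return arr


def decorrelation_stretch(
    img: np.ndarray, *, quantize: bool = True
) -> np.ndarray:
    """Whiten inter-channel correlation and restretch to the original
    per-channel standard deviations.

    The transform is the classical remote-sensing decorrelation stretch:
    compute the 3x3 channel covariance over all pixels, apply the symmetric
    (ZCA) whitening ``V diag(1/sqrt(lambda)) V^T``, rescale component ``j`` by
    the original channel standard deviation ``sigma_j`` and restore the
    channel means.  The output covariance is therefore exactly diagonal in the
    float domain.

    Parameters
    ----------
    img:
        H x W x 3 integer raster in [0, 255].
    quantize:
        When True (default) the result is clipped to [0, 255] and rounded to
        ``uint8``.  When False the raw float result is returned, which is the
        domain in which the decorrelation guarantee holds exactly.

    Returns
    -------
    The stretched image.  A constant-colour image (singular covariance) is
    returned unchanged and a :class:`DegenerateImageWarning` is emitted —
    there is nothing to decorrelate.
    """
    arr = _as_rgb(img)
    flat = arr.reshape(-1, 3).astype(np.float64)
    mu = flat.mean(axis=0)
    cov = np.cov(flat, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[0] <= 1e-10 * evals[-1]:
        warnings.warn(
            "singular channel covariance (constant or near-constant image); "
            "returning the input unchanged",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return arr.copy()
    whiten = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    target_std = np.sqrt(np.diag(cov))
    out = (flat - mu) @ whiten * target_std + mu
    out = out.reshape(arr.shape)
    if not quantize:
        return out
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def binarize_green(img: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Threshold the green channel at ``k`` times its whole-patch mean.

    Ties are kept as plant (``>=``).  An all-plant or all-background result is
    legal but logged as a warning, since it usually means a mis-set ``k``.
    """
    arr = _as_rgb(img)
    green = arr[:, :, 1].astype(np.float64)
    mask = green >= cfg.k * green.mean()
    if mask.all() or not mask.any():
        logger.warning(
            "binarize_green produced an %s mask (k=%.3f) — threshold ratio "
            "is likely mis-set for this patch",
            "all-plant" if mask.all() else "all-background",
            cfg.k,
        )
    return mask


def remove_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Delete connected components with area strictly below ``min_area``.

    Components are 8-connected; a component whose area equals ``min_area``
    exactly is kept.  No pixel is ever added.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if min_area <= 1 or not mask.any():
        return mask.copy()
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False  # background label
    return keep[labels]


def crop(img: np.ndarray, top: int, left: int, height: int, width: int) -> np.ndarray:
    """Rectangle crop of a patch out of a larger frame (hill trimming is a
    manual step; this is the only cropping aid provided)."""
    arr = np.asarray(img)
    if height < 1 or width < 1:
        raise ValueError("crop size must be positive")
    if top < 0 or left < 0 or top + height > arr.shape[0] or left + width > arr.shape[1]:
        raise ValueError("crop rectangle outside image bounds")
    return arr[top : top + height, left : left + width].copy()


def load_image(path) -> np.ndarray:
    """Read a JPG/PNG patch as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG (0 background / 255 plant)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)
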