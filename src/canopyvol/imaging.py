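"""Canopy image handling: GMR computation, threshold segmentation, canopy cover.

The segmentation statistic is GMR, the per-pixel difference between the green
and red channel digital numbers (DNs). Green vegetation reflects more in the
green band than in the red band, while soil and water have nearly equal green
and red DNs, so thresholding GMR separates canopy from background. A pixel
belongs to the canopy when its GMR value is *strictly greater* than the
threshold; canopy cover (CC) is the fraction of canopy pixels in the frame.

GMR operates on raw 8-bit DNs — no radiometric calibration, smoothing or
cropping is applied; images are processed whole.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .errors import ImageFormatError, ValidationError

#: Default GMR segmentation threshold (DN units). Threshold 30 also removes
#: darker canopy regions, so 10 is the operating point; 30 remains available
#: for sensitivity checks.
DEFAULT_THRESHOLD = 10


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB photograph as an ``(H, W, 3)`` uint8 array (R, G, B)."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"expected an (H, W, 3) pixel array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must contain at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GMRMap:
    """Per-pixel green-minus-red DN difference, signed, in [-255, 255]."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int16))


@dataclass(frozen=True)
class CanopyMask:
    """Boolean canopy mask with the pixel counts behind the CC statistic.

    ``n_plant`` is the number of canopy (True) pixels and ``n_total`` the
    total pixel count, so CC = n_plant / n_total.
    """

    mask: np.ndarray
    threshold_used: int | None = None
    n_plant: int = field(init=False)
    n_total: int = field(init=False)

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "n_plant", int(m.sum()))
        object.__setattr__(self, "n_total", int(m.size))


def read_image(path: str | os.PathLike) -> RGBImage:
    """Read a JPEG or PNG photograph into an :class:`RGBImage`.

    An alpha channel is dropped. Grayscale or palette images raise
    :class:`ImageFormatError` rather than being silently promoted.
    """
    with Image.open(path) as im:
        if im.mode == "RGBA":
            im = im.convert("RGB")
        if im.mode != "RGB":
            raise ImageFormatError(
                f"{path}: expected a 3-channel RGB image, got mode {im.mode!r}"
            )
        return RGBImage(np.asarray(im, dtype=np.uint8))


def write_image(image: RGBImage, path: str | os.PathLike) -> None:
    """Write an RGB image to ``path`` (format inferred from the suffix)."""
    Image.fromarray(image.pixels, mode="RGB").save(path)


def compute_gmr(image: RGBImage) -> GMRMap:
    """Per-pixel G - R difference on raw DNs; negatives are preserved."""
    px = image.pixels.astype(np.int16)
    return GMRMap(px[:, :, 1] - px[:, :, 0])


def segment_gmr(gmr: GMRMap, threshold: int = DEFAULT_THRESHOLD) -> CanopyMask:
    """Threshold a GMR map into a canopy mask.

    A pixel is canopy iff its GMR value is strictly greater than
    ``threshold``; pixels exactly at the threshold are background.
    """
    if not (-255 <= threshold <= 255):
        raise ValidationError(f"threshold {threshold} outside [-255, 255]")
    return CanopyMask(gmr.values > threshold, threshold_used=int(threshold))


def segment_image(image: RGBImage, threshold: int = DEFAULT_THRESHOLD) -> CanopyMask:
    """Convenience: GMR computation followed by threshold segmentation."""
    return segment_gmr(compute_gmr(image), threshold)


def canopy_cover(mask: CanopyMask) -> float:
    """Canopy cover CC = N_p / N_sum, the fraction of canopy pixels."""
    if mask.n_total < 1:
        raise ValidationError("canopy cover undefined for an empty image")
    return mask.n_plant / mask.n_total


def write_mask(mask: CanopyMask, path: str | os.PathLike) -> None:
    """Save a mask as an 8-bit grayscale PNG (canopy 255, background 0)."""
    Image.fromarray(np.where(mask.mask, 255, 0).astype(np.uint8), mode="L").save(
        path, format="PNG"
    )


def read_mask(path: str | os.PathLike) -> CanopyMask:
    """Read a mask written by :func:`write_mask` (nonzero pixels = canopy)."""
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("L")
        return CanopyMask(np.asarray(im) > 0)
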