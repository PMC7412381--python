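"""Image feature extraction: canopy cover plus ten RGB vegetation indices.

Each vegetation index (VI) is a scalar function of the mean red, green and
blue digital numbers of a pixel set. Indices are computed twice per image:
"before segmentation" from all pixels, and "after segmentation" from canopy
pixels only. Canopy cover (CC) exists only after segmentation, giving 21
features per image.

The ten indices:

========  =============================================  =====================
name      formula (on channel means R, G, B)             meaning
========  =============================================  =====================
INT       (R + G + B) / 3                                colour intensity
NBI       B / (R + G + B)                                normalized blueness
NGI       G / (R + G + B)                                normalized greenness
NRI       R / (R + G + B)                                normalized redness
GRRI      G / R                                          green-red ratio
GBRI      G / B                                          green-blue ratio
NGRDI     (G - R) / (G + R)                              norm. green-red diff.
NGBDI     (G - B) / (G + B)                              norm. green-blue diff.
EXG       2G - R - B                                     excess green
VDVI      (2G - R - B) / (2G + R + B)                    visible-band diff. VI
========  =============================================  =====================

The canonical path computes channel means first and applies each formula
once per image (means-first); a per-pixel variant (formula per pixel, then
averaged) is available for sensitivity checks but is not used in the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .imaging import CanopyMask, RGBImage, canopy_cover, segment_image

#: Declaration order of the ten vegetation indices.
VI_NAMES: tuple[str, ...] = (
    "INT",
    "NBI",
    "NGI",
    "NRI",
    "GRRI",
    "GBRI",
    "NGRDI",
    "NGBDI",
    "EXG",
    "VDVI",
)

#: Declaration order of the full 21-feature vector: CC, then the ten VIs
#: from all pixels, then the ten VIs from canopy pixels only.
FEATURE_ORDER: tuple[str, ...] = (
    ("cc",)
    + tuple(f"{n}_before" for n in VI_NAMES)
    + tuple(f"{n}_after" for n in VI_NAMES)
)


@dataclass(frozen=True)
class ChannelMeans:
    """Mean DN per channel over a stated pixel set."""

    r_mean: float
    g_mean: float
    b_mean: float
    n_pixels: int

    def __post_init__(self):
        if self.n_pixels < 1:
            raise ValidationError("channel means require at least one pixel")
        for v in (self.r_mean, self.g_mean, self.b_mean):
            if not 0.0 <= v <= 255.0:
                raise ValidationError(f"channel mean {v} outside [0, 255]")


@dataclass
class FeatureVector:
    """Per-image record of CC and the ten VIs before/after segmentation.

    Missing (undefined) index values are stored as NaN, e.g. the
    after-segmentation block of an image with no canopy pixels.
    """

    image_id: str
    cc: float
    vi_before: dict[str, float]
    vi_after: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {"cc": self.cc}
        out.update({f"{n}_before": self.vi_before[n] for n in VI_NAMES})
        out.update({f"{n}_after": self.vi_after[n] for n in VI_NAMES})
        return out


def channel_means(image: RGBImage, mask: CanopyMask | None = None) -> ChannelMeans:
    """Mean R, G, B DNs over all pixels, or over canopy pixels if a mask
    is given.

    Raises :class:`DegenerateInputError` for a mask with no canopy pixels.
    """
    px = image.pixels
    if mask is None:
        sel = px.reshape(-1, 3)
    else:
        if mask.mask.shape != px.shape[:2]:
            raise ValidationError(
                f"mask shape {mask.mask.shape} does not match image "
                f"{px.shape[:2]}"
            )
        if mask.n_plant < 1:
            raise DegenerateInputError("mask selects no canopy pixels")
        sel = px[mask.mask]
    means = sel.mean(axis=0)
    return ChannelMeans(float(means[0]), float(means[1]), float(means[2]), sel.shape[0])


def compute_vi(name: str, means: ChannelMeans) -> float:
    """Apply one index formula to a set of channel means.

    Zero denominators raise :class:`DegenerateInputError`; an index value is
    never silently infinite.
    """
    r, g, b = means.r_mean, means.g_mean, means.b_mean
    total = r + g + b
    if name == "INT":
        return total / 3.0
    if name in ("NBI", "NGI", "NRI"):
        if total == 0:
            raise DegenerateInputError(f"{name} undefined: R + G + B = 0")
        return {"NBI": b, "NGI": g, "NRI": r}[name] / total
    if name == "GRRI":
        if r == 0:
            raise DegenerateInputError("GRRI undefined: R = 0")
        return g / r
    if name == "GBRI":
        if b == 0:
            raise DegenerateInputError("GBRI undefined: B = 0")
        return g / b
    if name == "NGRDI":
        if g + r == 0:
            raise DegenerateInputError("NGRDI undefined: G + R = 0")
        return (g - r) / (g + r)
    if name == "NGBDI":
        if g + b == 0:
            raise DegenerateInputError("NGBDI undefined: G + B = 0")
        return (g - b) / (g + b)
    if name == "EXG":
        return 2.0 * g - r - b
    if name == "VDVI":
        if 2.0 * g + r + b == 0:
            raise DegenerateInputError("VDVI undefined: 2G + R + B = 0")
        return (2.0 * g - r - b) / (2.0 * g + r + b)
    raise ValidationError(f"unknown vegetation index {name!r}")


def compute_all_vis(means: ChannelMeans) -> dict[str, float]:
    """All ten indices from one set of channel means; undefined entries
    become NaN so a batch run completes and reports which indices failed."""
    out = {}
    for name in VI_NAMES:
        try:
            out[name] = compute_vi(name, means)
        except DegenerateInputError:
            out[name] = math.nan
    return out


def compute_vi_per_pixel(name: str, image: RGBImage, mask: CanopyMask | None = None) -> float:
    """Sensitivity-check variant: apply the formula per pixel, then average.

    Not used in the pipeline; the canonical path is means-first.
    """
    px = image.pixels if mask is None else image.pixels[mask.mask]
    px = px.reshape(-1, 3).astype(np.float64)
    if px.shape[0] == 0:
        raise DegenerateInputError("empty pixel set")
    vals = np.array(
        [
            compute_vi(name, ChannelMeans(r, g, b, 1))
            for r, g, b in px
        ]
    )
    return float(vals.mean())


def extract_features(
    image: RGBImage,
    threshold: int = 10,
    image_id: str = "",
) -> FeatureVector:
    """Segment at ``threshold`` and compute the 21-feature vector.

    Before-segmentation VIs use all pixels; after-segmentation VIs use
    canopy pixels only. An image with no canopy pixels gets CC = 0 and a
    NaN after-segmentation block — values are flagged missing, never
    fabricated.
    """
    mask = segment_image(image, threshold)
    cc = canopy_cover(mask)
    vi_before = compute_all_vis(channel_means(image))
    if mask.n_plant == 0:
        vi_after = {name: math.nan for name in VI_NAMES}
    else:
        vi_after = compute_all_vis(channel_means(image, mask))
    return FeatureVector(image_id=image_id, cc=cc, vi_before=vi_before, vi_after=vi_after)
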