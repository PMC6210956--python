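"""Device-independent segmentation on the b* channel of CIE L*a*b*.

A blue backboard has strongly negative b* (blue-yellow opponent axis) while
the yellow fiducial circle and green/red/yellow fruit all sit at b* >= ~0,
so a single global Otsu threshold on b* separates foreground from board
across phones and lighting. Working in b* makes the split approximately
invariant to luminance scaling (shadows, exposure).

Cleaning follows segmentation: an area filter drops small debris, a stalk
filter (morphological opening with a disk) removes thin peduncle-like
protrusions, and a final 1-px-radius dilation smooths the outline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color, measure, morphology
from skimage.filters import threshold_otsu

from .exceptions import NoThresholdError, UnsupportedImageError

__all__ = [
    "Component",
    "SegmentationResult",
    "to_bstar",
    "bstar_to_u8",
    "otsu_segment",
    "clean_mask",
    "segment_image",
    "DEFAULT_MIN_AREA_FRAC",
    "DEFAULT_STALK_WIDTH_FRAC",
]

# Defaults encode the prior that fruit are much larger than stalks/debris;
# both are overridable through the pipeline config.
DEFAULT_MIN_AREA_FRAC = 0.001   # of total image pixels
DEFAULT_STALK_WIDTH_FRAC = 0.02  # of image width


def to_bstar(image: np.ndarray) -> np.ndarray:
    """Return the b* channel of an 8-bit RGB image (sRGB primaries, D65 white).

    Output is float on the unscaled b* axis (roughly -128..+127): pure blue
    maps near -108, pure yellow near +94, achromatic grays to 0.
    """
    if image.ndim != 3 or image.shape[2] < 3:
        raise UnsupportedImageError(
            f"expected a 3-channel RGB raster, got shape {getattr(image, 'shape', None)}"
        )
    rgb = np.asarray(image)[..., :3]
    if rgb.dtype != np.uint8:
        raise UnsupportedImageError(f"expected 8-bit/channel input, got dtype {rgb.dtype}")
    return color.rgb2lab(rgb)[..., 2]


def bstar_to_u8(bstar: np.ndarray) -> np.ndarray:
    """Affinely rescale b* to 8-bit (b* + 128, clipped), the common library convention."""
    return np.clip(np.rint(np.asarray(bstar, dtype=float) + 128.0), 0, 255).astype(np.uint8)


@dataclass
class Component:
    """One connected component of the cleaned foreground mask."""

    label: int
    area_px: int
    contour: np.ndarray          # external contour, (N, 2) array of (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    centroid: tuple[float, float]
    slice: tuple                 # numpy slice locating the component in the full image
    mask: np.ndarray = field(repr=False)  # boolean mask within `slice`

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this component on the full image canvas."""
        out = np.zeros(shape, dtype=bool)
        out[self.slice] = self.mask
        return out


@dataclass
class SegmentationResult:
    """Foreground mask, the 8-bit Otsu threshold on b*, and connected components."""

    foreground_mask: np.ndarray
    threshold_bstar: int
    components: list[Component]


def otsu_segment(bstar: np.ndarray) -> tuple[np.ndarray, int]:
    """Threshold b* by Otsu's method; foreground is the high-b* class.

    b* is quantized to 8-bit before building the 256-bin histogram, and the
    returned threshold is on that 8-bit scale. The mask is the strict
    ``b8 > threshold`` set (blue board below, fruit and circle above).

    Raises
    ------
    NoThresholdError
        If the raster is constant.
    """
    b8 = bstar_to_u8(bstar)
    if b8.min() == b8.max():
        raise NoThresholdError("constant raster: between-class variance is undefined")
    thresh = int(threshold_otsu(b8, nbins=256))
    return b8 > thresh, thresh


def _opening_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    # Opening with a Euclidean disk, computed via two distance transforms;
    # equivalent to erode/dilate with disk(radius) but fast for large radii.
    if radius <= 0:
        return mask.copy()
    eroded = ndi.distance_transform_edt(mask) > radius
    if not eroded.any():
        return eroded
    return ndi.distance_transform_edt(~eroded) <= radius


def clean_mask(mask: np.ndarray, min_area_px: int, stalk_width_px: int) -> np.ndarray:
    """Remove debris and stalks from a binary mask, then smooth with a 1-px dilation.

    Steps, in order:

    1. connected components with fewer than ``min_area_px`` pixels are removed;
    2. each surviving component is opened with a disk of radius
       ``stalk_width_px / 2``, which erases protrusions (fruit peduncles)
       narrower than ``stalk_width_px``; only the largest opened piece of each
       component is kept, and components thinner than a stalk everywhere vanish;
    3. a final dilation with a 1-px-radius disk smooths the outline.

    An empty mask passes through empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels_all = measure.label(mask, connectivity=2)
    areas = np.bincount(labels_all.ravel())
    areas[0] = 0
    kept = (areas >= max(int(min_area_px), 1))[labels_all]
    if not kept.any():
        return kept

    radius = stalk_width_px / 2.0
    pad = int(math.ceil(radius)) + 1
    labels = measure.label(kept, connectivity=2)
    out = np.zeros_like(kept)
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
        r1p, c1p = min(r1 + pad, kept.shape[0]), min(c1 + pad, kept.shape[1])
        window = (slice(r0p, r1p), slice(c0p, c1p))
        sub = labels[window] == region.label
        opened = _opening_disk(sub, radius)
        if not opened.any():
            continue
        pieces = measure.label(opened, connectivity=2)
        if pieces.max() > 1:
            largest = np.argmax(np.bincount(pieces.ravel())[1:]) + 1
            opened = pieces == largest
        out[window] |= opened
    return morphology.dilation(out, morphology.disk(1))


def _external_contour(local_mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    # Pad so the contour closes even when the component touches the crop edge;
    # the longest contour is the external one (holes are ignored).
    padded = np.pad(local_mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    ext = max(contours, key=len)
    return ext - 1.0 + np.asarray(offset, dtype=float)


def segment_image(
    image: np.ndarray,
    min_area_px: int | None = None,
    stalk_width_px: int | None = None,
) -> SegmentationResult:
    """Full segmentation: RGB -> b* -> Otsu -> clean -> connected components.

    ``min_area_px`` defaults to 0.1% of the image pixels and ``stalk_width_px``
    to 2% of the image width.
    """
    bstar = to_bstar(image)
    raw_mask, thresh = otsu_segment(bstar)
    h, w = raw_mask.shape
    if min_area_px is None:
        min_area_px = int(round(DEFAULT_MIN_AREA_FRAC * h * w))
    if stalk_width_px is None:
        stalk_width_px = int(round(DEFAULT_STALK_WIDTH_FRAC * w))
    cleaned = clean_mask(raw_mask, min_area_px, stalk_width_px)

    components: list[Component] = []
    labels = measure.label(cleaned, connectivity=2)
    for region in measure.regionprops(labels):
        local = region.image
        components.append(
            Component(
                label=int(region.label),
                area_px=int(region.area),
                contour=_external_contour(local, region.bbox[:2]),
                bbox=tuple(int(v) for v in region.bbox),
                centroid=tuple(float(v) for v in region.centroid),
                slice=region.slice,
                mask=local,
            )
        )
    return SegmentationResult(foreground_mask=cleaned, threshold_bstar=thresh, components=components)
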