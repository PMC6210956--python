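"""Object identification: reference circle vs. fruit, shape class, QC gates.

Every cleaned component gets a moment-based fitted ellipse. The fiducial is
the circle-like component (eccentricity at or below the tilt gate) whose
diameter best matches the size predicted from the configured working
distance and the known circle diameter; the fruit is the largest remaining
component. Eccentricity of the fitted ellipse,

    epsilon = sqrt(1 - (b/a)^2),

is 0 for a circle and grows toward 1 as the shape elongates. A tilted
camera images the circle as an ellipse, so the reference eccentricity
doubles as a tilt gate (epsilon <= 0.3, roughly a 14 deg tilt); fruit
eccentricity selects the allometric shape class (near-circular apple and
citrus vs. elongated mango and avocado).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure, morphology

from .exceptions import ContactError, DegenerateInputError, NoFruitError, NoReferenceError
from .segment import SegmentationResult

__all__ = [
    "DetectedObject",
    "QCReport",
    "eccentricity",
    "detect_objects",
    "identify_objects",
    "classify_fruit",
    "components_adjacent",
    "DEFAULT_TILT_GATE",
    "DEFAULT_ELLIPSE_GATE",
]

#: Reference-circle eccentricity above which the camera is considered tilted
#: out of specification (documented as roughly a 14 deg camera-plane angle).
DEFAULT_TILT_GATE = 0.3
#: Fruit-shape gate: eccentricity above this selects the ellipsoid
#: (mango/avocado) allometry, at or below the sphere (apple/citrus) one.
DEFAULT_ELLIPSE_GATE = 0.35

ROLE_REFERENCE = "reference_circle"
ROLE_FRUIT = "fruit"
ROLE_UNASSIGNED = "unassigned"


def eccentricity(major_px: float, minor_px: float) -> float:
    """Eccentricity of an ellipse from its major/minor axis lengths.

    ``sqrt(1 - (b/a)^2)``: 0 for a circle, -> 1 for a degenerate line.

    Raises
    ------
    DegenerateInputError
        If ``minor_px <= 0``.
    ValueError
        If the axes are out of order (``minor > major``).
    """
    if minor_px <= 0:
        raise DegenerateInputError(f"minor axis must be positive, got {minor_px}")
    if minor_px > major_px:
        raise ValueError(f"axis order violated: minor {minor_px} > major {major_px}")
    return math.sqrt(1.0 - (minor_px / major_px) ** 2)


@dataclass
class DetectedObject:
    """A segmented component with its fitted ellipse and assigned role."""

    label: int
    area_px: int
    contour: np.ndarray = field(repr=False)
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    ellipse_major_px: float
    ellipse_minor_px: float
    eccentricity: float
    slice: tuple = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)
    role: str = ROLE_UNASSIGNED

    @property
    def bbox_height_px(self) -> int:
        """Bounding-box height = fruit image length L_i (px)."""
        return self.bbox[2] - self.bbox[0]

    @property
    def bbox_width_px(self) -> int:
        """Bounding-box width = fruit image width W_i (px)."""
        return self.bbox[3] - self.bbox[1]

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slice] = self.mask
        return out


def detect_objects(segmentation: SegmentationResult) -> list[DetectedObject]:
    """Fit a moment-based ellipse to every component of a segmentation."""
    labels = measure.label(segmentation.foreground_mask, connectivity=2)
    by_label = {r.label: r for r in measure.regionprops(labels)}
    objects: list[DetectedObject] = []
    for comp in segmentation.components:
        region = by_label.get(comp.label)
        if region is None:  # component bookkeeping must match the mask
            continue
        major = float(region.axis_major_length)
        minor = float(region.axis_minor_length)
        ecc = eccentricity(major, minor) if minor > 0 else 1.0
        objects.append(
            DetectedObject(
                label=comp.label,
                area_px=comp.area_px,
                contour=comp.contour,
                bbox=comp.bbox,
                centroid=comp.centroid,
                ellipse_major_px=major,
                ellipse_minor_px=minor,
                eccentricity=ecc,
                slice=comp.slice,
                mask=comp.mask,
            )
        )
    return objects


def components_adjacent(a: DetectedObject, b: DetectedObject, shape: tuple[int, int]) -> bool:
    """True if the two components' pixel sets are 8-connected-adjacent."""
    mask_a = a.full_mask(shape)
    mask_b = b.full_mask(shape)
    grown = morphology.dilation(mask_a, np.ones((3, 3), dtype=bool))
    return bool(np.any(grown & mask_b))


def identify_objects(
    objects: list[DetectedObject],
    expected_circle_px: float,
    tilt_gate: float = DEFAULT_TILT_GATE,
    image_shape: tuple[int, int] | None = None,
) -> tuple[DetectedObject, DetectedObject]:
    """Split components into (reference circle, fruit).

    The reference is the component with eccentricity at or below
    ``tilt_gate`` whose minor-axis diameter is closest to
    ``expected_circle_px`` (the projected circle size at the middle of the
    working distance range); the fruit is the largest remaining component
    by area. Contact between the two (8-connected adjacency) is a rejection.

    A single surviving component is ambiguous: a blob far larger than the
    expected circle and too elongated to be the circle itself is taken as a
    fruit merged with the fiducial (contact); anything else means the
    fiducial was not found.
    """
    if len(objects) < 2:
        if len(objects) == 1:
            blob = objects[0]
            expected_area = math.pi * expected_circle_px**2 / 4.0
            if blob.area_px > 3.0 * expected_area and blob.eccentricity > tilt_gate:
                raise ContactError(
                    "single merged component: fruit and reference circle appear to be in contact"
                )
            raise NoReferenceError("only one component segmented; reference circle not identified")
        raise NoReferenceError("no components segmented")

    candidates = [o for o in objects if o.eccentricity <= tilt_gate]
    if not candidates:
        raise NoReferenceError(
            f"no circle-like component (eccentricity <= {tilt_gate}) found among {len(objects)}"
        )
    ref = min(candidates, key=lambda o: abs(o.ellipse_minor_px - expected_circle_px))
    rest = [o for o in objects if o is not ref]
    if not rest:
        raise NoFruitError("no component left after assigning the reference circle")
    fruit = max(rest, key=lambda o: o.area_px)

    if image_shape is not None and components_adjacent(ref, fruit, image_shape):
        raise ContactError("fruit and reference circle are in contact")

    ref = replace(ref, role=ROLE_REFERENCE)
    fruit = replace(fruit, role=ROLE_FRUIT)
    return ref, fruit


def classify_fruit(obj: DetectedObject, ellipse_gate: float = DEFAULT_ELLIPSE_GATE) -> str:
    """Assign the allometric shape class from fruit eccentricity.

    ``eccentricity > ellipse_gate`` -> "ellipsoid" (mango/avocado);
    at or below the gate -> "sphere" (apple/citrus/mandarin).
    """
    return "ellipsoid" if obj.eccentricity > ellipse_gate else "sphere"


@dataclass(frozen=True)
class QCReport:
    """Quality-control gates applied before a measurement is accepted.

    tilt_ok: reference-circle eccentricity within the tilt gate;
    distance_ok: estimated camera distance inside the working range;
    contact_ok: fruit and circle components disjoint.
    """

    tilt_ok: bool
    distance_ok: bool
    contact_ok: bool

    @property
    def overall(self) -> bool:
        return self.tilt_ok and self.distance_ok and self.contact_ok
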