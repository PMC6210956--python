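"""Fruit sizing: thin-lens conversion with iterative allometric depth correction.

The fiducial gives the distance u to the *backboard*, but the fruit's imaged
perimeter sits roughly half a fruit-thickness in front of it. Thickness is
not observable in a single view, so it is estimated from the allometric
relation T_r = c * W_r (c = 0.88 for mango/avocado ellipsoids, 1.0 for
spherical apple/citrus) and the projection is re-evaluated at the corrected
distance (u - T_r/2) until the width estimate stabilises:

    W_0 = (u/f) p W_i,   W_{n+1} = ((u - c W_n / 2)/f) p W_i.

This is a linear fixed-point iteration with contraction ratio c*k/2
(k = p W_i / f ~ W_r/u << 1), so it converges geometrically — in practice
within five passes — to W* = u k / (1 + c k / 2). Length is corrected with
the same final (u - T_r/2).

Also here: the t-statistic sample-size rule for surveying a fruit
population to a target precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .camera import CameraIntrinsics
from .exceptions import ConfigurationError, ConvergenceError, DegenerateInputError
from .objects import DetectedObject, QCReport

__all__ = [
    "AllometryModel",
    "FruitMeasurement",
    "measure_fruit",
    "sample_size",
    "allometry_for_class",
    "DEFAULT_ALLOMETRY_SLOPES",
    "MANGO_CULTIVAR_SLOPES",
    "DEFAULT_TOL_MM",
    "DEFAULT_MAX_ITERATIONS",
    "DEFAULT_EDGE_COMPENSATION_PX",
]

#: Thickness/width slopes by shape class. Mango cultivars pooled give 0.88,
#: also applied to avocado; apple, citrus and mandarin are treated as spheres.
DEFAULT_ALLOMETRY_SLOPES = {"ellipsoid": 0.88, "sphere": 1.0}

#: Per-cultivar thickness-vs-width slopes (zero-intercept regressions on
#: caliper measurements of 387 mango fruit), shipped as documented
#: alternatives to the pooled 0.88.
MANGO_CULTIVAR_SLOPES = {
    "honey_gold": 0.82,
    "kp": 0.87,
    "calypso": 0.90,
    "keitt": 0.82,
    "all": 0.88,
}

DEFAULT_TOL_MM = 0.1          # below caliper repeatability (~1.2 mm)
DEFAULT_MAX_ITERATIONS = 20
#: Pixels subtracted from fitted diameters and bounding boxes to undo the
#: outline-smoothing dilation (1 px radius -> 2 px on any diameter).
DEFAULT_EDGE_COMPENSATION_PX = 2.0


@dataclass(frozen=True)
class AllometryModel:
    """Per-shape-class thickness model T_r = c * W_r."""

    fruit_class: str
    slope_c: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.slope_c <= 1.2:
            raise ConfigurationError(f"allometric slope must lie in [0, 1.2], got {self.slope_c}")


def allometry_for_class(fruit_class: str, slopes: dict[str, float] | None = None) -> AllometryModel:
    """Look up the allometry for a shape class ("ellipsoid" or "sphere")."""
    table = DEFAULT_ALLOMETRY_SLOPES if slopes is None else slopes
    if fruit_class not in table:
        raise ConfigurationError(f"unknown fruit class {fruit_class!r}; known: {sorted(table)}")
    return AllometryModel(fruit_class, table[fruit_class])


@dataclass(frozen=True)
class FruitMeasurement:
    """Converged real-world fruit dimensions with provenance."""

    length_mm: float
    width_mm: float
    thickness_mm: float
    distance_mm: float            # camera to backboard plane
    corrected_distance_mm: float  # camera to fruit mid-thickness plane
    iterations: int
    fruit_class: str
    qc: QCReport | None = field(default=None, compare=False)


def measure_fruit(
    fruit: DetectedObject,
    u_mm: float,
    intrinsics: CameraIntrinsics,
    allometry: AllometryModel,
    tol_mm: float = DEFAULT_TOL_MM,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    edge_compensation_px: float = DEFAULT_EDGE_COMPENSATION_PX,
    qc: QCReport | None = None,
) -> FruitMeasurement:
    """Real fruit length/width/thickness from its bounding box at distance u.

    L_i and W_i are the axis-aligned bounding-box height and width (the fruit
    long axis aligns with the board long axis in normal use), less the
    dilation compensation. The allometric depth correction iterates until the
    width changes by less than ``tol_mm``; ``iterations`` counts the
    projection evaluations that moved the estimate (1 for a flat object).

    Raises
    ------
    DegenerateInputError
        If the compensated bounding box is not strictly positive.
    ConvergenceError
        If the iteration cannot contract (c*k/2 >= 1, geometrically absurd)
        or does not converge within ``max_iterations``.
    """
    if u_mm <= 0:
        raise DegenerateInputError(f"distance must be positive, got {u_mm}")
    L_i = fruit.bbox_height_px - edge_compensation_px
    W_i = fruit.bbox_width_px - edge_compensation_px
    if L_i <= 0 or W_i <= 0:
        raise DegenerateInputError(
            f"bounding box {fruit.bbox_height_px} x {fruit.bbox_width_px} px degenerate "
            f"after {edge_compensation_px} px edge compensation"
        )

    scale = intrinsics.effective_pixel_size_mm / intrinsics.focal_length_mm  # mm per px per mm of u
    k_w = scale * W_i
    k_l = scale * L_i
    c = allometry.slope_c
    if c * k_w / 2.0 >= 1.0:
        raise ConvergenceError(
            f"contraction ratio c*k/2 = {c * k_w / 2.0:.3f} >= 1; geometry inconsistent"
        )

    width = u_mm * k_w
    iterations = 1
    converged = c == 0.0
    while not converged:
        new_width = (u_mm - c * width / 2.0) * k_w
        if abs(new_width - width) < tol_mm:
            width = new_width
            converged = True
        else:
            width = new_width
            iterations += 1
            if iterations > max_iterations:
                raise ConvergenceError(f"width did not converge in {max_iterations} iterations")

    thickness = c * width
    u_corrected = u_mm - thickness / 2.0
    length = u_corrected * k_l
    return FruitMeasurement(
        length_mm=length,
        width_mm=width,
        thickness_mm=thickness,
        distance_mm=u_mm,
        corrected_distance_mm=u_corrected,
        iterations=iterations,
        fruit_class=allometry.fruit_class,
        qc=qc,
    )


def sample_size(sd_mm: float, error_mm: float, t_value: float = 1.96) -> int:
    """Fruit count needed to estimate a population mean to ``error_mm``.

    ``n = ceil((t * SD / e)^2)`` with t = 1.96 for 95% confidence. Rounded
    up so the target precision is met.
    """
    if sd_mm <= 0 or error_mm <= 0 or t_value <= 0:
        raise DegenerateInputError("sd_mm, error_mm and t_value must all be positive")
    return math.ceil((t_value * sd_mm / error_mm) ** 2)
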