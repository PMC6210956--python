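"""Thin-lens camera geometry: pixel pitch, fiducial distance, pixel-to-mm conversion.

The model is the far-field thin-lens magnification m = f/u. Three relations
drive everything downstream:

* pixel pitch from the field of view:  ``p = 2 f tan(theta/2) / W_m``
  where ``W_m`` is the sensor pixel count along one axis (CMOS cells are
  square, so one axis suffices);
* camera-to-reference-plane distance from the imaged fiducial circle of
  known diameter ``D`` and fitted pixel diameter ``phi``:  ``u = f D / (phi p)``;
* real object size from image size:  ``X_r = (u / f) p X_i``.

Phones usually capture at a lower resolution than the native sensor
(pixel binning); the effective pixel pitch at capture resolution is the
native pitch scaled by the sensor/capture pixel-count ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ConfigurationError, DegenerateInputError

__all__ = [
    "CameraIntrinsics",
    "DistanceEstimate",
    "pixel_size",
    "estimate_distance",
    "image_to_real",
    "real_to_image",
    "HTC_DESIRE_820",
]


def pixel_size(focal_length_mm: float, pixel_count: int, view_angle_deg: float) -> float:
    """Pixel pitch (mm) from focal length, sensor pixel count and view angle.

    ``p = 2 f tan(theta/2) / W_m`` along a single axis; sensor cells are
    assumed square.

    Raises
    ------
    ConfigurationError
        If ``f <= 0``, ``W_m < 1`` or the view angle is outside (0, 180) deg.
    """
    if focal_length_mm <= 0:
        raise ConfigurationError(f"focal length must be positive, got {focal_length_mm}")
    if pixel_count < 1:
        raise ConfigurationError(f"pixel count must be >= 1, got {pixel_count}")
    if not 0.0 < view_angle_deg < 180.0:
        raise ConfigurationError(f"view angle must lie in (0, 180) deg, got {view_angle_deg}")
    return 2.0 * focal_length_mm * math.tan(math.radians(view_angle_deg) / 2.0) / pixel_count


@dataclass(frozen=True)
class CameraIntrinsics:
    """Optical constants defining the pixel-to-mm mapping of one camera.

    Either the horizontal view angle or the native pixel pitch may be the
    primary datum; use :meth:`from_view_angle` or :meth:`from_pixel_pitch`.
    ``capture_width_px``/``capture_height_px`` are the pixel counts of the
    image actually recorded, which may be binned down from the sensor.

    Attributes
    ----------
    focal_length_mm : float
        Optical focal length f.
    sensor_width_px, sensor_height_px : int
        Native sensor pixel counts.
    pixel_size_mm : float
        Native (unbinned) pixel pitch p.
    capture_width_px, capture_height_px : int
        Resolution of captured images.
    """

    focal_length_mm: float
    sensor_width_px: int
    sensor_height_px: int
    pixel_size_mm: float
    capture_width_px: int
    capture_height_px: int

    def __post_init__(self) -> None:
        if self.focal_length_mm <= 0:
            raise ConfigurationError("focal_length_mm must be positive")
        if self.pixel_size_mm <= 0:
            raise ConfigurationError("pixel_size_mm must be positive")
        for name in ("sensor_width_px", "sensor_height_px", "capture_width_px", "capture_height_px"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    @classmethod
    def from_pixel_pitch(
        cls,
        focal_length_mm: float,
        sensor_width_px: int,
        sensor_height_px: int,
        pixel_size_mm: float,
        capture_width_px: int | None = None,
        capture_height_px: int | None = None,
    ) -> "CameraIntrinsics":
        """Build intrinsics from a known native pixel pitch (view angle derived)."""
        return cls(
            focal_length_mm=focal_length_mm,
            sensor_width_px=sensor_width_px,
            sensor_height_px=sensor_height_px,
            pixel_size_mm=pixel_size_mm,
            capture_width_px=capture_width_px if capture_width_px is not None else sensor_width_px,
            capture_height_px=capture_height_px if capture_height_px is not None else sensor_height_px,
        )

    @classmethod
    def from_view_angle(
        cls,
        focal_length_mm: float,
        sensor_width_px: int,
        sensor_height_px: int,
        view_angle_h_deg: float,
        capture_width_px: int | None = None,
        capture_height_px: int | None = None,
    ) -> "CameraIntrinsics":
        """Build intrinsics from the horizontal field-of-view angle (pitch derived)."""
        p = pixel_size(focal_length_mm, sensor_width_px, view_angle_h_deg)
        return cls.from_pixel_pitch(
            focal_length_mm, sensor_width_px, sensor_height_px, p, capture_width_px, capture_height_px
        )

    @property
    def view_angle_h_deg(self) -> float:
        """Horizontal field of view implied by the pixel pitch (informational)."""
        return math.degrees(
            2.0 * math.atan(self.sensor_width_px * self.pixel_size_mm / (2.0 * self.focal_length_mm))
        )

    @property
    def binning_factor(self) -> float:
        """Sensor-to-capture pixel-count ratio along the horizontal axis."""
        return self.sensor_width_px / self.capture_width_px

    @property
    def effective_pixel_size_mm(self) -> float:
        """Pixel pitch that applies to images at the capture resolution."""
        return self.pixel_size_mm * self.binning_factor

    def at_capture_resolution(self, width_px: int, height_px: int) -> "CameraIntrinsics":
        """Same optics with a different capture (binned) resolution."""
        return CameraIntrinsics(
            self.focal_length_mm,
            self.sensor_width_px,
            self.sensor_height_px,
            self.pixel_size_mm,
            width_px,
            height_px,
        )


@dataclass(frozen=True)
class DistanceEstimate:
    """Camera-to-reference-plane distance recovered from the fiducial circle."""

    u_mm: float
    circle_diameter_px: float
    reference_diameter_mm: float

    def __post_init__(self) -> None:
        if self.u_mm <= 0:
            raise DegenerateInputError("distance must be positive")


def estimate_distance(
    circle_diameter_px: float,
    reference_diameter_mm: float,
    intrinsics: CameraIntrinsics,
) -> DistanceEstimate:
    """Distance u (mm) from camera to the reference plane, ``u = f D / (phi p)``.

    Uses the effective pixel pitch of the capture resolution, so the fitted
    diameter must be measured on a capture-resolution image.
    """
    if circle_diameter_px <= 0:
        raise DegenerateInputError(f"circle diameter must be positive, got {circle_diameter_px}")
    if reference_diameter_mm <= 0:
        raise DegenerateInputError(f"reference diameter must be positive, got {reference_diameter_mm}")
    u = (
        intrinsics.focal_length_mm
        * reference_diameter_mm
        / (circle_diameter_px * intrinsics.effective_pixel_size_mm)
    )
    return DistanceEstimate(u, circle_diameter_px, reference_diameter_mm)


def image_to_real(dimension_px: float, u_mm: float, intrinsics: CameraIntrinsics) -> float:
    """Convert a capture-resolution pixel dimension to mm at distance u: ``(u/f) p X_i``."""
    if u_mm <= 0:
        raise DegenerateInputError(f"distance must be positive, got {u_mm}")
    return u_mm / intrinsics.focal_length_mm * intrinsics.effective_pixel_size_mm * dimension_px


def real_to_image(dimension_mm: float, u_mm: float, intrinsics: CameraIntrinsics) -> float:
    """Inverse of :func:`image_to_real`: mm at distance u to capture pixels."""
    if u_mm <= 0:
        raise DegenerateInputError(f"distance must be positive, got {u_mm}")
    return dimension_mm * intrinsics.focal_length_mm / (u_mm * intrinsics.effective_pixel_size_mm)


#: Primary camera of the HTC Desire 820 used for the trial work: f = 3.81 mm,
#: native 4224 x 3136 px sensor with 2.377 um pixel-bin size, capturing at
#: 1920 x 1080. The implied ~106 deg horizontal FOV is informational only;
#: (f, p) is the authoritative pair.
HTC_DESIRE_820 = CameraIntrinsics.from_pixel_pitch(
    focal_length_mm=3.81,
    sensor_width_px=4224,
    sensor_height_px=3136,
    pixel_size_mm=0.002377,
    capture_width_px=1920,
    capture_height_px=1080,
)
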