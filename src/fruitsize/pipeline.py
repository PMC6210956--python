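"""Batch measurement pipeline: image file -> segmented objects -> QC -> CSV record.

One image yields one :class:`MeasurementRecord`, accepted or rejected. QC
failures (tilt, working distance, fruit-fiducial contact, missing objects)
produce rejection records with a reason instead of raising, so a batch
never dies on a bad frame. Timestamp and GPS coordinates are copied from
EXIF when the file carries them, or supplied per batch.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import ExifTags, Image

from . import objects as obj
from . import segment as seg
from .camera import CameraIntrinsics, estimate_distance
from .exceptions import (
    ConfigurationError,
    ContactError,
    FruitSizeError,
    NoFruitError,
    NoReferenceError,
)
from .sizing import (
    DEFAULT_ALLOMETRY_SLOPES,
    DEFAULT_EDGE_COMPENSATION_PX,
    DEFAULT_MAX_ITERATIONS,
    DEFAULT_TOL_MM,
    allometry_for_class,
    measure_fruit,
)

__all__ = [
    "PipelineConfig",
    "MeasurementRecord",
    "BatchSummary",
    "load_camera_config",
    "save_camera_config",
    "process_array",
    "process_image",
    "process_batch",
    "write_csv",
    "read_csv",
    "CSV_COLUMNS",
]

log = logging.getLogger(__name__)

#: Working camera-to-board distance band (mm): closer crops the scene,
#: farther is impractical with board and phone in either hand.
DEFAULT_MIN_DISTANCE_MM = 120.0
DEFAULT_MAX_DISTANCE_MM = 300.0


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs besides the image itself."""

    intrinsics: CameraIntrinsics
    circle_diameter_mm: float = 40.0
    min_distance_mm: float = DEFAULT_MIN_DISTANCE_MM
    max_distance_mm: float = DEFAULT_MAX_DISTANCE_MM
    tilt_gate: float = obj.DEFAULT_TILT_GATE
    ellipse_gate: float = obj.DEFAULT_ELLIPSE_GATE
    fruit_class: str = "auto"        # "auto" | "sphere" | "ellipsoid"
    allometry_slopes: dict = field(default_factory=lambda: dict(DEFAULT_ALLOMETRY_SLOPES))
    min_area_px: int | None = None   # None -> 0.1% of image pixels
    stalk_width_px: int | None = None  # None -> 2% of image width
    tol_mm: float = DEFAULT_TOL_MM
    max_iterations: int = DEFAULT_MAX_ITERATIONS
    edge_compensation_px: float = DEFAULT_EDGE_COMPENSATION_PX
    latitude: str = ""               # batch-level fallback when EXIF has no GPS
    longitude: str = ""

    def __post_init__(self) -> None:
        if self.circle_diameter_mm <= 0:
            raise ConfigurationError("circle_diameter_mm must be positive")
        if not 0 < self.min_distance_mm < self.max_distance_mm:
            raise ConfigurationError("need 0 < min_distance_mm < max_distance_mm")
        if self.fruit_class not in ("auto", "sphere", "ellipsoid"):
            raise ConfigurationError(f"fruit_class must be auto/sphere/ellipsoid, got {self.fruit_class}")

    @property
    def expected_circle_px(self) -> float:
        """Projected fiducial diameter at the middle of the working range."""
        u_mid = 0.5 * (self.min_distance_mm + self.max_distance_mm)
        i = self.intrinsics
        return i.focal_length_mm * self.circle_diameter_mm / (u_mid * i.effective_pixel_size_mm)


_CONFIG_KEYS = (
    "focal_length_mm",
    "sensor_width_px",
    "sensor_height_px",
    "view_angle_h_deg",
    "pixel_size_um",
    "capture_width_px",
    "capture_height_px",
)


def load_camera_config(path: str | Path) -> CameraIntrinsics:
    """Read camera intrinsics from a flat ``key = value`` file.

    Either ``pixel_size_um`` or ``view_angle_h_deg`` must be present; the
    missing one is derived. Lines starting with ``#`` are comments.
    """
    values: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = float(value.strip())

    required = ("focal_length_mm", "sensor_width_px", "sensor_height_px")
    missing = [k for k in required if k not in values]
    if missing:
        raise ConfigurationError(f"{path}: missing keys {missing}")
    common = dict(
        focal_length_mm=values["focal_length_mm"],
        sensor_width_px=int(values["sensor_width_px"]),
        sensor_height_px=int(values["sensor_height_px"]),
        capture_width_px=int(values["capture_width_px"]) if "capture_width_px" in values else None,
        capture_height_px=int(values["capture_height_px"]) if "capture_height_px" in values else None,
    )
    if "pixel_size_um" in values:
        return CameraIntrinsics.from_pixel_pitch(pixel_size_mm=values["pixel_size_um"] / 1000.0, **common)
    if "view_angle_h_deg" in values:
        return CameraIntrinsics.from_view_angle(view_angle_h_deg=values["view_angle_h_deg"], **common)
    raise ConfigurationError(f"{path}: need either pixel_size_um or view_angle_h_deg")


def save_camera_config(intrinsics: CameraIntrinsics, path: str | Path) -> None:
    """Write intrinsics in the flat ``key = value`` format read by :func:`load_camera_config`."""
    i = intrinsics
    Path(path).write_text(
        "# Camera intrinsics\n"
        f"focal_length_mm = {i.focal_length_mm}\n"
        f"sensor_width_px = {i.sensor_width_px}\n"
        f"sensor_height_px = {i.sensor_height_px}\n"
        f"pixel_size_um = {i.pixel_size_mm * 1000.0}\n"
        f"capture_width_px = {i.capture_width_px}\n"
        f"capture_height_px = {i.capture_height_px}\n"
    )


@dataclass(frozen=True)
class MeasurementRecord:
    """One CSV row: per-fruit size, provenance metadata, and QC outcome.

    Size fields are ``None`` when the image was rejected, in which case
    ``reject_reason`` is non-empty.
    """

    timestamp: str = ""
    latitude: str = ""
    longitude: str = ""
    image_path: str = ""
    fruit_class: str = ""
    length_mm: float | None = None
    width_mm: float | None = None
    thickness_mm: float | None = None
    distance_mm: float | None = None
    qc_overall: bool = False
    reject_reason: str = ""


CSV_COLUMNS = [
    "timestamp",
    "latitude",
    "longitude",
    "image_path",
    "fruit_class",
    "length_mm",
    "width_mm",
    "thickness_mm",
    "distance_mm",
    "qc_overall",
    "reject_reason",
]


def process_array(
    image: np.ndarray,
    config: PipelineConfig,
    image_path: str = "",
    timestamp: str = "",
    latitude: str = "",
    longitude: str = "",
) -> MeasurementRecord:
    """Run the full pipeline on an in-memory RGB image.

    Returns an accepted record with real dimensions, or a rejection record
    whose ``reject_reason`` names the failed gate.
    """
    meta = dict(
        timestamp=timestamp,
        latitude=latitude or config.latitude,
        longitude=longitude or config.longitude,
        image_path=image_path,
    )

    def rejection(reason: str) -> MeasurementRecord:
        return MeasurementRecord(qc_overall=False, reject_reason=reason, **meta)

    segmentation = seg.segment_image(image, config.min_area_px, config.stalk_width_px)
    detected = obj.detect_objects(segmentation)
    try:
        reference, fruit = obj.identify_objects(
            detected,
            config.expected_circle_px,
            tilt_gate=config.tilt_gate,
            image_shape=segmentation.foreground_mask.shape,
        )
    except ContactError:
        return rejection("fruit-reference contact")
    except NoReferenceError:
        # A component of roughly the fiducial's size whose eccentricity
        # exceeds the gate is a tilted fiducial: report tilt, not absence.
        for candidate in detected:
            size_ok = (
                0.6 * config.expected_circle_px
                <= candidate.ellipse_major_px
                <= 2.5 * config.expected_circle_px
            )
            if size_ok and candidate.eccentricity > config.tilt_gate:
                return rejection(
                    f"tilt out of range (reference eccentricity "
                    f"{candidate.eccentricity:.3f} > {config.tilt_gate})"
                )
        return rejection("no reference circle detected")
    except NoFruitError:
        return rejection("no fruit detected")

    # Distance from the reference minor axis (robust to tilt about the phone
    # long axis), compensated for the outline-smoothing dilation.
    diameter_px = reference.ellipse_minor_px - config.edge_compensation_px
    if diameter_px <= 0:
        return rejection("reference circle degenerate after edge compensation")
    distance = estimate_distance(diameter_px, config.circle_diameter_mm, config.intrinsics)

    tilt_ok = reference.eccentricity <= config.tilt_gate
    distance_ok = config.min_distance_mm <= distance.u_mm <= config.max_distance_mm
    qc = obj.QCReport(tilt_ok=tilt_ok, distance_ok=distance_ok, contact_ok=True)
    if not qc.overall:
        reasons = []
        if not tilt_ok:
            reasons.append(
                f"tilt out of range (reference eccentricity {reference.eccentricity:.3f} > "
                f"{config.tilt_gate})"
            )
        if not distance_ok:
            reasons.append(
                f"distance out of range ({config.min_distance_mm:.0f}-"
                f"{config.max_distance_mm:.0f} mm): estimated {distance.u_mm:.1f} mm"
            )
        return rejection("; ".join(reasons))

    fruit_class = (
        obj.classify_fruit(fruit, config.ellipse_gate)
        if config.fruit_class == "auto"
        else config.fruit_class
    )
    try:
        measurement = measure_fruit(
            fruit,
            distance.u_mm,
            config.intrinsics,
            allometry_for_class(fruit_class, config.allometry_slopes),
            tol_mm=config.tol_mm,
            max_iterations=config.max_iterations,
            edge_compensation_px=config.edge_compensation_px,
            qc=qc,
        )
    except FruitSizeError as exc:
        return rejection(f"measurement failed: {exc}")

    return MeasurementRecord(
        fruit_class=fruit_class,
        length_mm=measurement.length_mm,
        width_mm=measurement.width_mm,
        thickness_mm=measurement.thickness_mm,
        distance_mm=measurement.distance_mm,
        qc_overall=True,
        reject_reason="",
        **meta,
    )


def _exif_metadata(path: Path) -> tuple[str, str, str]:
    """(ISO timestamp, latitude, longitude) from EXIF; empty strings when absent."""
    timestamp = latitude = longitude = ""
    try:
        with Image.open(path) as im:
            exif = im.getexif()
            if not exif:
                return timestamp, latitude, longitude
            exif_ifd = exif.get_ifd(ExifTags.IFD.Exif)
            raw_ts = exif_ifd.get(ExifTags.Base.DateTimeOriginal) or exif.get(
                ExifTags.Base.DateTime
            )
            if raw_ts:
                date, _, time = str(raw_ts).partition(" ")
                timestamp = f"{date.replace(':', '-')}T{time}" if time else date.replace(":", "-")
            gps = exif.get_ifd(ExifTags.IFD.GPSInfo)
            if gps:
                lat = _gps_decimal(gps.get(2), gps.get(1), negative_ref="S")
                lon = _gps_decimal(gps.get(4), gps.get(3), negative_ref="W")
                latitude = "" if lat is None else f"{lat:.6f}"
                longitude = "" if lon is None else f"{lon:.6f}"
    except Exception:  # metadata is best-effort; never fail a measurement over it
        log.debug("EXIF read failed for %s", path, exc_info=True)
    return timestamp, latitude, longitude


def _gps_decimal(dms, ref, negative_ref: str) -> float | None:
    if not dms:
        return None
    try:
        deg, minute, sec = (float(v) for v in dms)
    except (TypeError, ValueError):
        return None
    value = deg + minute / 60.0 + sec / 3600.0
    return -value if ref == negative_ref else value


def process_image(path: str | Path, config: PipelineConfig) -> MeasurementRecord:
    """Load an image file (with EXIF metadata when present) and measure it.

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    """
    path = Path(path)
    with Image.open(path) as im:
        rgb = np.asarray(im.convert("RGB"))
    timestamp, latitude, longitude = _exif_metadata(path)
    return process_array(
        rgb,
        config,
        image_path=str(path),
        timestamp=timestamp,
        latitude=latitude,
        longitude=longitude,
    )


@dataclass(frozen=True)
class BatchSummary:
    accepted: int
    rejected: int

    @property
    def total(self) -> int:
        return self.accepted + self.rejected


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.3f}"
    return str(value)


def write_csv(records: list[MeasurementRecord], path: str | Path) -> None:
    """Write records as UTF-8 comma-separated values with a header row."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow([_format_value(getattr(rec, col)) for col in CSV_COLUMNS])


def read_csv(path: str | Path) -> list[MeasurementRecord]:
    """Parse a CSV written by :func:`write_csv` back into records."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                MeasurementRecord(
                    timestamp=row["timestamp"],
                    latitude=row["latitude"],
                    longitude=row["longitude"],
                    image_path=row["image_path"],
                    fruit_class=row["fruit_class"],
                    length_mm=float(row["length_mm"]) if row["length_mm"] else None,
                    width_mm=float(row["width_mm"]) if row["width_mm"] else None,
                    thickness_mm=float(row["thickness_mm"]) if row["thickness_mm"] else None,
                    distance_mm=float(row["distance_mm"]) if row["distance_mm"] else None,
                    qc_overall=row["qc_overall"] == "true",
                    reject_reason=row["reject_reason"],
                )
            )
    return records


def process_batch(
    paths: list[str | Path],
    config: PipelineConfig,
    out_csv: str | Path,
) -> BatchSummary:
    """Measure every image, write one CSV row per input in order, return counts.

    Per-image failures (unreadable files included) become rejection rows;
    the batch itself only fails if the CSV cannot be written.
    """
    if not paths:
        raise ConfigurationError("process_batch needs at least one input path")
    records = []
    for path in paths:
        try:
            record = process_image(path, config)
        except Exception as exc:
            log.warning("failed to process %s: %s", path, exc)
            record = MeasurementRecord(
                image_path=str(path), qc_overall=False, reject_reason=f"processing error: {exc}"
            )
        records.append(record)
    write_csv(records, out_csv)
    accepted = sum(1 for r in records if r.qc_overall)
    return BatchSummary(accepted=accepted, rejected=len(records) - accepted)
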