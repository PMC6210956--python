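"""Synthetic scene renderer with exact ground truth.

Renders the field setup the pipeline expects — a blue A4 backboard carrying
a yellow fiducial circle, with one ellipsoidal fruit in front of it — under
a pinhole projection consistent with the camera intrinsics, so every
pipeline stage can be verified without a camera.

Geometry: the board (and the circle in its plane) sits at distance u from
the lens; the fruit silhouette is the mid-cross-section ellipse of an
ellipsoid of length L, width W and thickness T, drawn at depth (u - T/2) —
exactly the perimeter plane the sizing model assumes. Optional camera pitch
tilts the board plane about a horizontal axis and is modelled
orthographically: vertical extents shrink by cos(tilt), so a circle of
diameter D images with eccentricity sin(tilt). Optional degradations:
multiplicative shading over the left half of the scene, Gaussian boundary
blur, and seeded pixel noise.

Ground-truth masks are hard (pixel-center) classifications that partition
the frame into {board, circle, fruit, outside}; the rendered image uses a
1-px linear edge blend (a blur radius of 2 emulates the ~4 px yellow/blue
boundary blur seen at 200 mm on a real phone).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from itertools import product
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .camera import CameraIntrinsics
from .exceptions import ConfigurationError

__all__ = [
    "RenderParams",
    "SceneTruth",
    "SyntheticScene",
    "render",
    "scene_grid",
    "save_scene",
    "FRUIT_COLORS",
]

FRUIT_COLORS = {
    "green": (60, 160, 50),
    "red": (190, 45, 40),
    "yellow": (225, 205, 45),
}


@dataclass(frozen=True)
class RenderParams:
    """Scene description in physical units plus image-degradation settings.

    Positions are (x, y) offsets in mm within the board plane, x rightward
    and y downward from the board centre. ``fruit_thickness_mm=None`` uses
    the mango allometry T = 0.88 W. ``shadow_factor`` multiplies intensity
    left of the fruit centre (1.0 = no shadow); ``blur_px`` is a Gaussian
    sigma; ``noise_sigma`` is additive per-channel Gaussian noise driven by
    ``seed``.
    """

    u_mm: float = 200.0
    circle_diameter_mm: float = 40.0
    fruit_length_mm: float = 100.0
    fruit_width_mm: float = 80.0
    fruit_thickness_mm: float | None = None
    include_fruit: bool = True
    tilt_deg: float = 0.0
    board_width_mm: float = 297.0
    board_height_mm: float = 210.0
    fruit_center_mm: tuple[float, float] = (-60.0, 0.0)
    circle_center_mm: tuple[float, float] = (90.0, 0.0)
    board_color: tuple[int, int, int] = (30, 60, 200)
    circle_color: tuple[int, int, int] = (240, 220, 30)
    fruit_color: tuple[int, int, int] = FRUIT_COLORS["green"]
    outside_color: tuple[int, int, int] = (15, 30, 150)  # shaded board edge filling the margin
    edge_blend_px: float = 1.0
    blur_px: float = 0.0
    noise_sigma: float = 0.0
    shadow_factor: float = 1.0
    seed: int = 0

    @property
    def thickness_mm(self) -> float:
        if not self.include_fruit:
            return 0.0
        if self.fruit_thickness_mm is not None:
            return self.fruit_thickness_mm
        return 0.88 * self.fruit_width_mm


@dataclass
class SceneTruth:
    """Exact geometry behind a rendered scene."""

    u_mm: float
    circle_diameter_mm: float
    circle_diameter_px: float        # projected major axis (untilted diameter)
    circle_minor_px: float           # vertical axis after tilt foreshortening
    fruit_length_mm: float
    fruit_width_mm: float
    fruit_thickness_mm: float
    fruit_length_px: float           # projected at the mid-thickness plane
    fruit_width_px: float
    tilt_deg: float
    circle_center_px: tuple[float, float]
    fruit_center_px: tuple[float, float]
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def scalar_record(self) -> dict:
        d = asdict(self)
        d.pop("masks")
        return d


@dataclass
class SyntheticScene:
    """A rendered image paired with its ground truth and render settings."""

    image: np.ndarray
    truth: SceneTruth
    params: RenderParams


def _soft_ellipse(xx, yy, cx, cy, rx, ry, blend_px):
    # Coverage in [0,1] with a linear ramp of width `blend_px` across the
    # boundary; hard membership is coverage >= 0.5 evaluated at pixel centres.
    q = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    dist = (q - 1.0) * math.sqrt(rx * ry)  # approx signed distance, px
    if blend_px <= 0:
        return (dist <= 0).astype(float)
    return np.clip(0.5 - dist / blend_px, 0.0, 1.0)


def render(params: RenderParams, intrinsics: CameraIntrinsics) -> SyntheticScene:
    """Render a scene at the camera's capture resolution.

    Deterministic given ``params.seed``.

    Raises
    ------
    ConfigurationError
        If u is outside [50, 1000] mm or the fruit/circle does not fit on
        the board.
    """
    p = params
    if not 50.0 <= p.u_mm <= 1000.0:
        raise ConfigurationError(f"stand-off u={p.u_mm} mm outside the renderable [50, 1000] mm")
    T = p.thickness_mm
    if p.include_fruit:
        if (
            abs(p.fruit_center_mm[0]) + p.fruit_width_mm / 2.0 > p.board_width_mm / 2.0
            or abs(p.fruit_center_mm[1]) + p.fruit_length_mm / 2.0 > p.board_height_mm / 2.0
        ):
            raise ConfigurationError("fruit does not fit inside the board")
    if (
        abs(p.circle_center_mm[0]) + p.circle_diameter_mm / 2.0 > p.board_width_mm / 2.0
        or abs(p.circle_center_mm[1]) + p.circle_diameter_mm / 2.0 > p.board_height_mm / 2.0
    ):
        raise ConfigurationError("reference circle does not fit inside the board")

    w, h = intrinsics.capture_width_px, intrinsics.capture_height_px
    f = intrinsics.focal_length_mm
    pitch = intrinsics.effective_pixel_size_mm
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cos_t = math.cos(math.radians(p.tilt_deg))

    def scale(z_mm: float) -> float:  # px per mm at depth z
        return f / (z_mm * pitch)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    s_u = scale(p.u_mm)
    bw2, bh2 = p.board_width_mm / 2.0 * s_u, p.board_height_mm / 2.0 * s_u * cos_t
    board_hard = (np.abs(xx - cx) <= bw2) & (np.abs(yy - cy) <= bh2)

    ccx = cx + p.circle_center_mm[0] * s_u
    ccy = cy + p.circle_center_mm[1] * s_u * cos_t
    crx = p.circle_diameter_mm / 2.0 * s_u
    cry = crx * cos_t
    circle_cov = _soft_ellipse(xx, yy, ccx, ccy, crx, cry, p.edge_blend_px)
    circle_hard = circle_cov >= 0.5

    if p.include_fruit:
        z_f = p.u_mm - T / 2.0
        if z_f <= f:
            raise ConfigurationError("fruit mid-plane would sit at or behind the lens")
        s_f = scale(z_f)
        fcx = cx + p.fruit_center_mm[0] * s_f
        fcy = cy + p.fruit_center_mm[1] * s_f * cos_t
        frx = p.fruit_width_mm / 2.0 * s_f
        fry = p.fruit_length_mm / 2.0 * s_f * cos_t
        fruit_cov = _soft_ellipse(xx, yy, fcx, fcy, frx, fry, p.edge_blend_px)
        fruit_hard = fruit_cov >= 0.5
    else:
        s_f, fcx, fcy, frx, fry = s_u, cx, cy, 0.0, 0.0
        fruit_cov = np.zeros((h, w))
        fruit_hard = np.zeros((h, w), dtype=bool)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = p.outside_color
    img[board_hard] = p.board_color
    for ch in range(3):
        img[..., ch] = img[..., ch] * (1 - circle_cov) + p.circle_color[ch] * circle_cov
        img[..., ch] = img[..., ch] * (1 - fruit_cov) + p.fruit_color[ch] * fruit_cov

    if p.shadow_factor != 1.0:
        split = int(round(fcx)) if p.include_fruit else w // 2
        img[:, :split, :] *= p.shadow_factor
    if p.blur_px > 0:
        img = ndi.gaussian_filter(img, sigma=(p.blur_px, p.blur_px, 0))
    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        img = img + rng.normal(0.0, p.noise_sigma, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    circle_mask = circle_hard & ~fruit_hard
    board_mask = board_hard & ~circle_hard & ~fruit_hard
    outside_mask = ~(board_mask | circle_mask | fruit_hard)
    truth = SceneTruth(
        u_mm=p.u_mm,
        circle_diameter_mm=p.circle_diameter_mm,
        circle_diameter_px=2.0 * crx,
        circle_minor_px=2.0 * cry,
        fruit_length_mm=p.fruit_length_mm if p.include_fruit else 0.0,
        fruit_width_mm=p.fruit_width_mm if p.include_fruit else 0.0,
        fruit_thickness_mm=T,
        fruit_length_px=2.0 * fry,
        fruit_width_px=2.0 * frx,
        tilt_deg=p.tilt_deg,
        circle_center_px=(ccx, ccy),
        fruit_center_px=(fcx, fcy),
        masks={
            "board": board_mask,
            "circle": circle_mask,
            "fruit": fruit_hard,
            "outside": outside_mask,
        },
    )
    return SyntheticScene(image=image, truth=truth, params=p)


def scene_grid(
    intrinsics: CameraIntrinsics,
    u_values: list[float],
    tilt_values: list[float] | None = None,
    fruit_dims: list[tuple[float, float, float | None]] | None = None,
    seeds: list[int] | None = None,
    base: RenderParams | None = None,
) -> list[SyntheticScene]:
    """Render the Cartesian product of stand-offs, tilts, fruit sizes and seeds.

    Empty/None tilt, fruit-size or seed ranges collapse to the base values.
    Reproducible: a fixed seed list yields a bit-identical image set.
    """
    if not u_values:
        raise ConfigurationError("u_values must be non-empty")
    base = base if base is not None else RenderParams()
    tilts = list(tilt_values) if tilt_values else [base.tilt_deg]
    dims = (
        list(fruit_dims)
        if fruit_dims
        else [(base.fruit_length_mm, base.fruit_width_mm, base.fruit_thickness_mm)]
    )
    seed_list = list(seeds) if seeds else [base.seed]
    scenes = []
    for u, tilt, (L, W, T), seed in product(u_values, tilts, dims, seed_list):
        scenes.append(
            render(
                replace(
                    base,
                    u_mm=u,
                    tilt_deg=tilt,
                    fruit_length_mm=L,
                    fruit_width_mm=W,
                    fruit_thickness_mm=T,
                    seed=seed,
                ),
                intrinsics,
            )
        )
    return scenes


def save_scene(scene: SyntheticScene, directory: str | Path, stem: str) -> tuple[Path, Path]:
    """Write the image as PNG plus a JSON sidecar with the scalar ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png = directory / f"{stem}.png"
    sidecar = directory / f"{stem}.json"
    iio.imwrite(png, scene.image)
    payload = {"truth": scene.truth.scalar_record(), "params": asdict(scene.params)}
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return png, sidecar
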