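"""Segmentation on the b* channel: colour conversion, Otsu thresholding, cleaning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fruitsize as fs
from fruitsize.exceptions import NoThresholdError, UnsupportedImageError
from fruitsize.segment import bstar_to_u8, clean_mask, otsu_segment, segment_image, to_bstar


def bstar_reference(rgb8):
    """Closed-form sRGB (D65) -> XYZ -> L*a*b* b* channel, independent oracle."""
    c = np.asarray(rgb8, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    m = np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
    xyz = m @ lin
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    fval = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    return 200.0 * (fval[1] - fval[2])


def otsu_bruteforce(u8):
    """Exhaustive argmax of between-class variance over the 256 8-bit levels."""
    hist = np.bincount(u8.ravel(), minlength=256).astype(float)
    total = hist.sum()
    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * np.arange(256))
    best_var, best_t = -1.0, None
    for t in range(255):
        w0, w1 = csum[t], total - csum[t]
        if w0 == 0 or w1 == 0:
            continue
        m0 = cmoment[t] / w0
        m1 = (cmoment[255] - cmoment[t]) / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestToBstar:
    @pytest.mark.parametrize(
        "rgb,expected,tol",
        [
            ((0, 0, 255), -107.86, 1.0),   # pure blue: strongly negative
            ((255, 255, 0), 94.48, 1.0),   # pure yellow: strongly positive
            ((128, 128, 128), 0.0, 0.01),  # achromatic axis
        ],
    )
    def test_primary_colours(self, rgb, expected, tol):
        img = np.full((2, 2, 3), rgb, dtype=np.uint8)
        assert to_bstar(img)[0, 0] == pytest.approx(expected, abs=tol)

    @given(
        st.tuples(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)),
    )
    def test_matches_closed_form_oracle(self, rgb):
        img = np.full((1, 1, 3), rgb, dtype=np.uint8)
        assert to_bstar(img)[0, 0] == pytest.approx(bstar_reference(rgb), abs=0.05)

    def test_rejects_grayscale_and_float_input(self):
        with pytest.raises(UnsupportedImageError):
            to_bstar(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(UnsupportedImageError):
            to_bstar(np.zeros((4, 4, 3), dtype=float))


class TestOtsu:
    def test_bimodal_raster_split(self):
        b = np.empty((10, 10))
        b[:5] = -100.0
        b[5:] = 90.0
        mask, thresh = otsu_segment(b)
        # Threshold strictly between the modes on the 8-bit scale;
        # foreground is the high-b* (yellow) class.
        assert 28 <= thresh < 218
        assert mask[5:].all() and not mask[:5].any()

    def test_constant_raster_has_no_threshold(self):
        with pytest.raises(NoThresholdError):
            otsu_segment(np.zeros((8, 8)))

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_equals_bruteforce_argmax(self, seed):
        rng = np.random.default_rng(seed)
        # Mixture of two diffuse classes, as b* histograms are in practice.
        b = np.concatenate(
            [rng.normal(-70, 15, size=600), rng.normal(50, 25, size=400)]
        ).reshape(40, 25)
        mask, thresh = otsu_segment(b)
        expected = otsu_bruteforce(bstar_to_u8(b))
        assert thresh == expected
        np.testing.assert_array_equal(mask, bstar_to_u8(b) > expected)

    def test_scene_threshold_equals_bruteforce(self, default_scene):
        b = to_bstar(default_scene.image)
        _, thresh = otsu_segment(b)
        assert thresh == otsu_bruteforce(bstar_to_u8(b))


def _ellipse_mask(shape, center, ry, rx):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - center[0]) / ry) ** 2 + ((xx - center[1]) / rx) ** 2 <= 1.0


class TestCleanMask:
    def test_small_speck_removed_large_ellipse_kept(self):
        mask = _ellipse_mask((300, 300), (150, 150), 60, 55)
        mask[5:11, 5:10] = True  # 30-px speck
        out = clean_mask(mask, min_area_px=100, stalk_width_px=0)
        assert not out[:20, :20].any()
        assert out[150, 150]

    def test_stalk_filter_removes_thin_protrusion(self):
        mask = _ellipse_mask((400, 300), (250, 150), 100, 70)
        mask[30:150, 147:153] = True  # 6-px-wide, 120-px-long stalk
        out = clean_mask(mask, min_area_px=100, stalk_width_px=10)
        # No stalk pixel survives beyond the 1-px dilation fringe of the body.
        assert not out[:140, :].any()
        # Body axis lengths change by <= 2 px.
        rows = np.where(out.any(axis=1))[0]
        cols = np.where(out.any(axis=0))[0]
        assert abs((rows[-1] - rows[0] + 1) - 201) <= 2
        assert abs((cols[-1] - cols[0] + 1) - 141) <= 2

    def test_smooth_mask_only_gains_dilation_ring(self):
        mask = _ellipse_mask((200, 200), (100, 100), 50, 40)
        out = clean_mask(mask, min_area_px=100, stalk_width_px=0)
        assert (out | mask).sum() == out.sum()  # output is a superset
        ring = out & ~mask
        # The ring hugs the boundary: every new pixel is 4-adjacent to the input.
        from scipy import ndimage as ndi

        grown = ndi.binary_dilation(mask, structure=ndi.generate_binary_structure(2, 1))
        assert not (ring & ~grown).any()

    def test_empty_mask_passes_through(self):
        out = clean_mask(np.zeros((50, 50), dtype=bool), 10, 4)
        assert not out.any()


class TestSegmentImage:
    def test_deterministic_bit_for_bit(self, default_scene):
        a = segment_image(default_scene.image)
        b = segment_image(default_scene.image)
        np.testing.assert_array_equal(a.foreground_mask, b.foreground_mask)
        assert a.threshold_bstar == b.threshold_bstar

    def test_fruit_and_circle_masks_recovered(self, default_scene, iou_fn):
        seg = segment_image(default_scene.image)
        truth_fg = default_scene.truth.masks["fruit"] | default_scene.truth.masks["circle"]
        assert iou_fn(seg.foreground_mask, truth_fg) >= 0.95
        assert len(seg.components) == 2

    def test_shadow_robustness(self, bench_cam, iou_fn):
        # A 40%-deep multiplicative shadow over half the fruit must not break
        # the global b* threshold.
        scene = fs.render(fs.RenderParams(shadow_factor=0.6), bench_cam)
        seg = segment_image(scene.image)
        truth = scene.truth.masks["fruit"]
        best = max(iou_fn(c.full_mask(truth.shape), truth) for c in seg.components)
        assert best >= 0.90

    @pytest.mark.parametrize("factor", [0.5, 0.7, 1.0])
    def test_luminance_scaling_leaves_mask_stable(self, default_scene, iou_fn, factor):
        truth = default_scene.truth.masks["fruit"]
        scaled = np.clip(default_scene.image.astype(float) * factor, 0, 255).astype(np.uint8)
        seg = segment_image(scaled)
        best = max(iou_fn(c.full_mask(truth.shape), truth) for c in seg.components)
        base = segment_image(default_scene.image)
        base_best = max(iou_fn(c.full_mask(truth.shape), truth) for c in base.components)
        assert abs(best - base_best) < 0.02
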