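"""Iterative allometric depth correction and survey sample sizes."""

import numpy as np
import pytest

import fruitsize as fs
from fruitsize.exceptions import ConfigurationError, ConvergenceError, DegenerateInputError
from fruitsize.objects import DetectedObject
from fruitsize.sizing import AllometryModel, allometry_for_class, measure_fruit, sample_size


def fruit_stub(height_px, width_px):
    return DetectedObject(
        label=1,
        area_px=int(0.78 * height_px * width_px),
        contour=np.zeros((4, 2)),
        bbox=(0, 0, height_px, width_px),
        centroid=(height_px / 2, width_px / 2),
        ellipse_major_px=float(height_px),
        ellipse_minor_px=float(width_px),
        eccentricity=0.6,
        role="fruit",
    )


def fixed_point_width(u_mm, w_i_px, c, intrinsics):
    """Algebraic fixed point of the depth correction: W* = u k / (1 + c k / 2)."""
    k = intrinsics.effective_pixel_size_mm / intrinsics.focal_length_mm * w_i_px
    return u_mm * k / (1.0 + c * k / 2.0)


class TestMeasureFruit:
    def test_flat_object_is_uncorrected_single_pass(self, htc):
        fruit = fruit_stub(402, 302)
        m = measure_fruit(fruit, 200.0, htc, AllometryModel("flat", 0.0), edge_compensation_px=2.0)
        k = htc.effective_pixel_size_mm / htc.focal_length_mm
        assert m.iterations == 1
        assert m.width_mm == pytest.approx(200.0 * k * 300, rel=1e-12)
        assert m.length_mm == pytest.approx(200.0 * k * 400, rel=1e-12)
        assert m.thickness_mm == 0.0
        assert m.corrected_distance_mm == m.distance_mm

    @pytest.mark.parametrize("u", [120.0, 160.0, 200.0, 240.0, 280.0, 300.0])
    def test_matches_algebraic_fixed_point(self, htc, u):
        # Mango-like: real width ~80 mm projected at distance u.
        w_i = fs.real_to_image(80.0, u, htc)
        fruit = fruit_stub(int(round(1.25 * w_i)) + 2, int(round(w_i)) + 2)
        m = measure_fruit(fruit, u, htc, AllometryModel("ellipsoid", 0.88), tol_mm=1e-7)
        expected = fixed_point_width(u, fruit.bbox_width_px - 2.0, 0.88, htc)
        assert m.width_mm == pytest.approx(expected, abs=1e-6)
        assert m.thickness_mm == pytest.approx(0.88 * m.width_mm, rel=1e-12)
        assert m.corrected_distance_mm == pytest.approx(u - m.thickness_mm / 2, rel=1e-12)

    def test_converges_within_five_iterations_at_operating_distance(self, htc):
        # Representative geometry: 80 mm mango imaged from 200 mm. Closer in
        # the working range the contraction ratio c*k/2 grows toward ~0.4 and
        # more passes are needed; that is exercised in the full-band test.
        u = 200.0
        w_i = fs.real_to_image(80.0, u - 35.2, htc)
        fruit = fruit_stub(int(round(1.25 * w_i)) + 2, int(round(w_i)) + 2)
        m = measure_fruit(fruit, u, htc, AllometryModel("ellipsoid", 0.88), tol_mm=0.1)
        assert m.iterations <= 5

    @pytest.mark.parametrize("u", [120.0, 200.0, 300.0])
    def test_converges_across_working_range(self, htc, u):
        w_i = fs.real_to_image(80.0, u - 35.2, htc)
        fruit = fruit_stub(int(round(1.25 * w_i)) + 2, int(round(w_i)) + 2)
        m = measure_fruit(fruit, u, htc, AllometryModel("ellipsoid", 0.88), tol_mm=0.1)
        assert m.iterations <= 20
        assert m.thickness_mm == pytest.approx(0.88 * m.width_mm, rel=1e-12)

    def test_iterates_contract_geometrically(self, htc):
        # Reference re-implementation of the update rule: the gap to the fixed
        # point shrinks by exactly c*k/2 each pass (alternating sign), and the
        # converged package value agrees with the limit.
        u, c = 200.0, 0.88
        w_i = 300.0
        k = htc.effective_pixel_size_mm / htc.focal_length_mm * w_i
        w_star = fixed_point_width(u, w_i, c, htc)
        w = u * k
        gaps = []
        for _ in range(8):
            gaps.append(w - w_star)
            w = (u - c * w / 2.0) * k
        ratios = [gaps[i + 1] / gaps[i] for i in range(len(gaps) - 1)]
        assert all(r == pytest.approx(-c * k / 2.0, rel=1e-9) for r in ratios)
        fruit = fruit_stub(402, 302)
        m = measure_fruit(fruit, u, htc, AllometryModel("ellipsoid", c), tol_mm=1e-9)
        assert m.width_mm == pytest.approx(w_star, abs=1e-7)

    def test_depth_correction_moves_width_toward_truth(self, bench_cam):
        # Rendered mango at 200 mm: the uncorrected width (flat model) must be
        # farther from truth than the allometric correction.
        scene = fs.render(fs.RenderParams(), bench_cam)
        seg = fs.segment_image(scene.image)
        objs = fs.detect_objects(seg)
        cfg = fs.PipelineConfig(intrinsics=bench_cam)
        ref, fruit = fs.identify_objects(
            objs, cfg.expected_circle_px, image_shape=seg.foreground_mask.shape
        )
        u = fs.estimate_distance(ref.ellipse_minor_px - 2.0, 40.0, bench_cam).u_mm
        flat = measure_fruit(fruit, u, bench_cam, AllometryModel("flat", 0.0))
        corrected = measure_fruit(fruit, u, bench_cam, AllometryModel("ellipsoid", 0.88))
        truth_w = scene.truth.fruit_width_mm
        assert abs(corrected.width_mm - truth_w) < abs(flat.width_mm - truth_w)

    def test_absurd_geometry_raises_convergence_error(self, htc):
        fruit = fruit_stub(3000, 2800)
        with pytest.raises(ConvergenceError):
            measure_fruit(fruit, 5000.0, htc, AllometryModel("ellipsoid", 1.2))

    def test_degenerate_bbox_rejected(self, htc):
        with pytest.raises(DegenerateInputError):
            measure_fruit(fruit_stub(2, 2), 200.0, htc, AllometryModel("sphere", 1.0))


class TestAllometry:
    def test_default_slopes(self):
        assert allometry_for_class("ellipsoid").slope_c == 0.88
        assert allometry_for_class("sphere").slope_c == 1.0

    def test_cultivar_table(self):
        assert fs.MANGO_CULTIVAR_SLOPES == {
            "honey_gold": 0.82,
            "kp": 0.87,
            "calypso": 0.90,
            "keitt": 0.82,
            "all": 0.88,
        }

    def test_slope_bounds(self):
        with pytest.raises(ConfigurationError):
            AllometryModel("x", 1.3)
        with pytest.raises(ConfigurationError):
            AllometryModel("x", -0.1)
        with pytest.raises(ConfigurationError):
            allometry_for_class("banana")


class TestSampleSize:
    @pytest.mark.parametrize(
        "sd,e,t,expected",
        [
            (18.7, 5.0, 1.96, 54),  # length survey
            (14.2, 5.0, 1.96, 31),  # width survey
            (5.0, 5.0, 1.0, 1),     # unit case
        ],
    )
    def test_survey_counts(self, sd, e, t, expected):
        assert sample_size(sd, e, t) == expected

    def test_rounds_up(self):
        # (t*SD/e)^2 = 4.41 -> 5 fruit needed, not 4.
        assert sample_size(10.5, 10.0, 2.0) == 5

    def test_positive_arguments_required(self):
        with pytest.raises(DegenerateInputError):
            sample_size(0.0, 5.0)
        with pytest.raises(DegenerateInputError):
            sample_size(10.0, -1.0)
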