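"""Shape descriptors against analytic and brute-force oracles."""

import math

import numpy as np
import pytest

from evquant import morphometry
from evquant.detect import VesicleDetection

from conftest import (
    capsule_mask,
    disk_mask,
    ellipse_mask,
    mask_to_detection,
    random_convex_polygon,
    regular_polygon,
)


def polygon_detection(vertices: np.ndarray, pixel_size_nm: float = 1.0) -> VesicleDetection:
    return VesicleDetection(
        contour=vertices, complete=True, source_id="poly",
        area_px=morphometry.polygon_area(vertices), pixel_size_nm=pixel_size_nm,
    )


def sweep_feret(vertices: np.ndarray, n_angles: int = 3600) -> tuple[float, float]:
    """Brute-force projection sweep over uniform angles plus the edge normals."""
    edges = np.roll(vertices, -1, axis=0) - vertices
    edge_angles = np.arctan2(edges[:, 1], edges[:, 0]) + np.pi / 2
    angles = np.concatenate([np.linspace(0, np.pi, n_angles, endpoint=False), edge_angles])
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = vertices @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()), float(widths.max())


class TestEquivalentDiameter:
    def test_digitized_circle(self):
        det = mask_to_detection(disk_mask(50.0), pixel_size_nm=1.0)
        assert morphometry.equivalent_diameter(det) == pytest.approx(100.0, rel=0.01)

    @pytest.mark.parametrize("side", [10.0, 37.5, 140.0])
    def test_square_against_shoelace_oracle(self, side):
        square = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float)
        det = polygon_detection(square, pixel_size_nm=2.0)
        # shoelace oracle computed term by term
        x, y = square[:, 0], square[:, 1]
        area = 0.5 * abs(sum(x[i] * y[(i + 1) % 4] - x[(i + 1) % 4] * y[i] for i in range(4)))
        assert area == pytest.approx(side**2)
        expected = 2 * side / math.sqrt(math.pi) * 2.0
        assert morphometry.equivalent_diameter(det) == pytest.approx(expected, rel=1e-9)

    def test_degenerate_polygon_rejected(self):
        line = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        det = VesicleDetection(contour=line, complete=True, source_id="x", area_px=1.0)
        with pytest.raises(ValueError, match="zero area"):
            morphometry.equivalent_diameter(det)


class TestFitEllipse:
    def test_circle_axes_equal_diameter(self):
        det = mask_to_detection(disk_mask(40.0))
        major, minor, _ = morphometry.fit_ellipse(det)
        assert major == pytest.approx(80.0, rel=0.01)
        assert minor == pytest.approx(80.0, rel=0.01)

    def test_two_to_one_ellipse(self):
        det = mask_to_detection(ellipse_mask(60.0, 30.0))
        major, minor, _ = morphometry.fit_ellipse(det)
        assert major / minor == pytest.approx(2.0, rel=0.02)

    @pytest.mark.parametrize("angle", [0, 17, 45, 73, 90, 128])
    def test_rectangle_axes_rotation_invariant(self, angle):
        # rotation-sweep oracle: axes of an L x W rectangle must not depend
        # on its orientation
        L, W = 80.0, 30.0
        base = np.array(
            [[-L / 2, -W / 2], [0, -W / 2], [L / 2, -W / 2], [L / 2, W / 2], [-L / 2, W / 2]]
        )  # redundant mid-edge vertex: same shape, >= 5 vertices
        t = math.radians(angle)
        rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        det = polygon_detection(base @ rot.T + 200.0)
        major, minor, _ = morphometry.fit_ellipse(det)
        # uniform rectangle: lambda_1 = L^2/12 -> major = 4 sqrt(lambda_1) = 2L/sqrt(3)
        assert major == pytest.approx(2 * L / math.sqrt(3), rel=0.01)
        assert minor == pytest.approx(2 * W / math.sqrt(3), rel=0.01)

    def test_collinear_contour_rejected(self):
        pts = np.column_stack([np.linspace(0, 10, 6), np.linspace(0, 20, 6)])
        det = VesicleDetection(contour=pts, complete=True, source_id="x", area_px=1.0)
        with pytest.raises(ValueError):
            morphometry.fit_ellipse(det)


class TestFeretDiameters:
    def test_circle_feret_equals_diameter(self):
        det = mask_to_detection(disk_mask(50.0), pixel_size_nm=1.0)
        fmin, fmax = morphometry.feret_diameters(det)
        assert fmin == pytest.approx(100.0, abs=1.5)
        assert fmax == pytest.approx(100.0, abs=1.5)

    def test_capsule_min_caliper_is_width(self):
        det = mask_to_detection(capsule_mask(42.0, 200.0, angle_deg=30.0), pixel_size_nm=1.0)
        fmin, fmax = morphometry.feret_diameters(det)
        assert fmin == pytest.approx(42.0, abs=1.5)
        assert fmax == pytest.approx(200.0, abs=2.0)

    def test_calipers_match_angle_sweep_on_random_convex_polygons(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            poly = random_convex_polygon(rng)
            det = polygon_detection(poly)
            fmin, fmax = morphometry.feret_diameters(det)
            smin, smax = sweep_feret(poly)
            assert abs(fmin - smin) < 1e-6
            assert abs(fmax - smax) < 1e-6

    def test_identical_points_rejected(self):
        pts = np.zeros((5, 2))
        det = VesicleDetection(contour=pts, complete=True, source_id="x", area_px=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            morphometry.feret_diameters(det)


class TestRoundness:
    def test_circle_is_one(self):
        det = mask_to_detection(disk_mask(50.0))
        assert morphometry.roundness(det) == pytest.approx(1.0, rel=0.01)

    def test_two_to_one_ellipse_is_half(self):
        det = mask_to_detection(ellipse_mask(60.0, 30.0))
        assert morphometry.roundness(det) == pytest.approx(0.5, rel=0.02)

    def test_long_capsule_against_pixel_mask_oracle(self):
        # oracle: weighted image moments of the filled mask itself
        mask = capsule_mask(30.0, 150.0)  # L = 5 W
        det = mask_to_detection(mask)
        value = morphometry.roundness(det)

        ys, xs = np.nonzero(mask)
        xc, yc = xs.mean(), ys.mean()
        u20 = ((xs - xc) ** 2).mean()
        u02 = ((ys - yc) ** 2).mean()
        u11 = ((xs - xc) * (ys - yc)).mean()
        lam1 = (u20 + u02) / 2 + math.sqrt((u20 - u02) ** 2 / 4 + u11**2)
        oracle = 4 * mask.sum() / (math.pi * (4 * math.sqrt(lam1)) ** 2)
        assert value == pytest.approx(oracle, rel=0.02)
        assert value < 0.6

    def test_classification_threshold_is_strict(self):
        assert morphometry.classify_tubular(0.59, 0.6) is True
        assert morphometry.classify_tubular(0.60, 0.6) is False

    def test_scale_invariance(self):
        small = mask_to_detection(disk_mask(25.0))
        big = mask_to_detection(disk_mask(50.0))
        assert morphometry.roundness(small) == pytest.approx(morphometry.roundness(big), rel=0.02)

    @pytest.mark.parametrize("angle", [0, 30, 90])
    def test_rotation_invariance_of_descriptors(self, angle):
        base = mask_to_detection(capsule_mask(60.0, 180.0, angle_deg=0))
        rot = mask_to_detection(capsule_mask(60.0, 180.0, angle_deg=angle))
        assert morphometry.roundness(rot) == pytest.approx(morphometry.roundness(base), rel=0.02)
        f_base = morphometry.feret_diameters(base)
        f_rot = morphometry.feret_diameters(rot)
        assert f_rot[0] == pytest.approx(f_base[0], rel=0.02)
        assert f_rot[1] == pytest.approx(f_base[1], rel=0.02)


class TestSummaries:
    def build_metric(self, diameter, roundness_val, complete=True):
        return morphometry.VesicleMetrics(
            vesicle_id="v", source_id="s", complete=complete, diameter_nm=diameter,
            major_axis_nm=diameter, minor_axis_nm=diameter * roundness_val,
            feret_max_nm=diameter, feret_min_nm=diameter * roundness_val,
            roundness=roundness_val,
            tubular=morphometry.classify_tubular(roundness_val) if complete else None,
        )

    def test_tubular_fraction_by_construction(self):
        metrics = [self.build_metric(100, 0.9) for _ in range(90)]
        metrics += [self.build_metric(100, 0.3) for _ in range(10)]
        s = morphometry.summarize_condition(metrics, "mixed")
        assert s.tubular_fraction == pytest.approx(0.10)
        assert s.tubular_count == 10
        assert s.n == s.n_complete == 100

    def test_single_vesicle_sd_is_missing_not_zero(self):
        s = morphometry.summarize_condition([self.build_metric(80, 0.95)], "one")
        assert s.sd_diameter_nm is None

    def test_incomplete_vesicles_excluded_from_tubular_denominator(self):
        metrics = [self.build_metric(100, 0.9), self.build_metric(100, 0.3)]
        metrics += [self.build_metric(100, 0.3, complete=False)] * 3
        s = morphometry.summarize_condition(metrics, "c")
        assert s.n == 5 and s.n_complete == 2
        assert s.tubular_fraction == pytest.approx(0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            morphometry.summarize_condition([], "none")


class TestSizeDistributionModes:
    def test_single_gaussian_gives_one_mode(self):
        rng = np.random.default_rng(42)
        x = rng.normal(100, 10, 500)
        modes = morphometry.size_distribution_modes(x)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(100, abs=3)

    def test_bimodal_mixture_gives_two_modes(self):
        rng = np.random.default_rng(43)
        x = np.concatenate([rng.normal(60, 8, 500), rng.normal(140, 15, 500)])
        modes = morphometry.size_distribution_modes(x)
        assert len(modes) == 2
        assert modes[0] == pytest.approx(60, abs=6)
        assert modes[1] == pytest.approx(140, abs=10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            morphometry.size_distribution_modes([1.0] * 9)

    def test_constant_sample_degenerates_to_single_mode(self):
        assert morphometry.size_distribution_modes([42.0] * 20) == [42.0]
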