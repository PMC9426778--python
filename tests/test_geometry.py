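import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiskeye.errors import FitError, GeometryError
from whiskeye.geometry import (
    CircleFit,
    EyeGeometry,
    fit_circle,
    fit_ellipse,
    fit_eye_geometry,
    fit_parabola,
    hue_centroid,
    normalize_pupil,
    to_polar_angle,
)

GREEN = (0.0, 1.0, 0.0)


def frame_with(pixels, shape=(32, 32)):
    """pixels: list of ((x, y), rgb)."""
    img = np.zeros(shape + (3,))
    for (x, y), rgb in pixels:
        img[y, x] = rgb
    return img


class TestHueCentroid:
    def test_single_green_pixel(self):
        img = frame_with([((10, 20), GREEN)])
        assert hue_centroid(img, (0.25, 0.42)) == pytest.approx((10.0, 20.0))

    def test_luma_weighted_mean(self):
        # two in-hue pixels, luma ratio 1:3 -> weighted x = 7.5
        img = frame_with([((0, 0), (0.0, 0.25, 0.0)), ((10, 0), (0.0, 0.75, 0.0))], shape=(4, 16))
        assert hue_centroid(img, (0.25, 0.42)) == pytest.approx((7.5, 0.0))

    def test_no_matching_pixels_is_missing(self):
        img = frame_with([((3, 3), (1.0, 0.0, 0.0))])  # red, outside window
        assert hue_centroid(img, (0.25, 0.42)) is None

    def test_min_pixels(self):
        img = frame_with([((3, 3), GREEN)])
        assert hue_centroid(img, (0.25, 0.42), min_pixels=2) is None

    def test_wrapping_window(self):
        img = frame_with([((5, 5), (1.0, 0.0, 0.1))])  # hue just below 1
        assert hue_centroid(img, (0.9, 0.1)) is not None

    def test_empty_image(self):
        with pytest.raises(FitError):
            hue_centroid(np.zeros((0, 0, 3)), (0.2, 0.4))


def circumcircle(p1, p2, p3):
    """Closed-form circumcircle oracle for exactly three points."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    r = np.hypot(ax - ux, ay - uy)
    return (ux, uy), r


class TestCircleFit:
    def test_exact_circle(self):
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.c_[5 + 3 * np.cos(ang), 5 + 3 * np.sin(ang)]
        fit = fit_circle(pts)
        assert fit.center == pytest.approx((5.0, 5.0))
        assert fit.radius == pytest.approx(3.0)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_three_points_match_circumcircle_oracle(self, rng):
        for _ in range(25):
            pts = rng.uniform(-10, 10, (3, 2))
            v1, v2 = pts[1] - pts[0], pts[2] - pts[0]
            if abs(v1[0] * v2[1] - v1[1] * v2[0]) < 1e-3:
                continue
            center, r = circumcircle(*pts)
            fit = fit_circle(pts)
            assert fit.center == pytest.approx(center, rel=1e-6)
            assert fit.radius == pytest.approx(r, rel=1e-6)

    def test_collinear_error(self):
        with pytest.raises(FitError):
            fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_residual_positive_off_circle(self, rng):
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.c_[np.cos(ang), np.sin(ang)] + rng.normal(0, 0.05, (12, 2))
        assert fit_circle(pts).residual > 0


class TestPolarAngle:
    def setup_method(self):
        self.fit = CircleFit(center=(2.0, 3.0), radius=4.0, residual=0.0)

    def test_zero_and_ninety(self):
        assert to_polar_angle((6.0, 3.0), self.fit) == pytest.approx(0.0)
        assert to_polar_angle((2.0, 7.0), self.fit) == pytest.approx(90.0)

    def test_against_atan2_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(-10, 10, 2)
            if np.allclose(p, self.fit.center):
                continue
            expect = np.degrees(np.arctan2(p[1] - 3.0, p[0] - 2.0))
            assert to_polar_angle(tuple(p), self.fit) == pytest.approx(expect)

    def test_protraction_sign(self):
        assert to_polar_angle((2.0, 7.0), self.fit, protraction_sign=-1.0) == pytest.approx(-90.0)


def ellipse_points(center, axes, theta=0.0, n=8, phase=0.3):
    t = phase + np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = axes[0] * np.cos(t)
    y = axes[1] * np.sin(t)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return (rot @ np.c_[x, y].T).T + center


class TestEllipseFit:
    def test_axis_aligned_recovery(self):
        fit = fit_ellipse(ellipse_points((3, 4), (2, 1)))
        assert fit.center == pytest.approx((3.0, 4.0), abs=1e-9)
        assert fit.semi_axes == pytest.approx((2.0, 1.0), abs=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-8)

    def test_rotated_recovery(self):
        fit = fit_ellipse(ellipse_points((0, 0), (3, 1), theta=0.7, n=10))
        assert fit.semi_axes == pytest.approx((3.0, 1.0), abs=1e-8)
        assert fit.orientation == pytest.approx(0.7, abs=1e-8)

    def test_circle_gives_equal_axes(self):
        fit = fit_ellipse(ellipse_points((1, 1), (2, 2)))
        assert fit.semi_axes[0] == pytest.approx(fit.semi_axes[1])
        assert fit.equivalent_diameter == pytest.approx(4.0)

    def test_diameters(self):
        fit = fit_ellipse(ellipse_points((0, 0), (4, 1)))
        assert fit.major_diameter == pytest.approx(8.0)
        assert fit.minor_diameter == pytest.approx(2.0)
        assert fit.equivalent_diameter == pytest.approx(4.0)

    def test_collinear_error(self):
        pts = np.c_[np.arange(8.0), 2 * np.arange(8.0)]
        with pytest.raises(FitError):
            fit_ellipse(pts)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_ellipse(ellipse_points((0, 0), (2, 1))[:4])


class TestEyeGeometry:
    def test_analytic_corners(self):
        # top y = -x^2 + 2, bottom y = x^2 -> corners (+-1, 1), width 2
        x = np.linspace(-2, 2, 9)
        geom = fit_eye_geometry(np.c_[x, -(x**2) + 2], np.c_[x, x**2])
        assert geom.corners[0] == pytest.approx((-1.0, 1.0))
        assert geom.corners[1] == pytest.approx((1.0, 1.0))
        assert geom.width == pytest.approx(2.0)

    def test_nasal_high_x_ordering(self):
        x = np.linspace(-2, 2, 9)
        geom = fit_eye_geometry(np.c_[x, -(x**2) + 2], np.c_[x, x**2], nasal="high_x")
        assert geom.corners[0] == pytest.approx((1.0, 1.0))

    def test_non_crossing_error(self):
        x = np.linspace(-2, 2, 9)
        with pytest.raises(GeometryError):
            fit_eye_geometry(np.c_[x, x**2 + 1], np.c_[x, x**2 + 2])

    def test_coincident_error(self):
        x = np.linspace(-2, 2, 9)
        with pytest.raises(GeometryError):
            fit_eye_geometry(np.c_[x, x**2], np.c_[x, x**2])

    def test_noisy_recovery_within_tolerance(self, rng):
        x = np.linspace(-2, 2, 25)
        top = np.c_[x, -(x**2) + 2 + rng.normal(0, 0.01, x.size)]
        bottom = np.c_[x, x**2 + rng.normal(0, 0.01, x.size)]
        geom = fit_eye_geometry(top, bottom)
        assert abs(geom.corners[0][0] - (-1.0)) < 0.05
        assert abs(geom.corners[0][1] - 1.0) < 0.05
        assert abs(geom.corners[1][0] - 1.0) < 0.05

    def test_parabola_needs_three_distinct_x(self):
        with pytest.raises(FitError):
            fit_parabola([(1, 0), (1, 1), (1, 2), (2, 3)])


class TestNormalizePupil:
    def setup_method(self):
        x = np.linspace(-2, 2, 9)
        self.geom = EyeGeometry(
            top_parabola=(0, 0, 1),
            bottom_parabola=(0, 0, -1),
            corners=((0.0, 0.0), (10.0, 0.0)),
            width=10.0,
        )

    def test_projection(self):
        assert normalize_pupil((3.0, 2.0), self.geom) == pytest.approx(0.3)

    def test_corners_exact(self):
        assert normalize_pupil((0.0, 0.0), self.geom) == 0.0
        assert normalize_pupil((10.0, 0.0), self.geom) == 1.0

    def test_perpendicular_offset_ignored(self):
        assert normalize_pupil((5.0, 7.0), self.geom) == pytest.approx(0.5)

    def test_not_clamped(self):
        assert normalize_pupil((12.0, 0.0), self.geom) == pytest.approx(1.2)


class TestSimilarityInvariance:
    @given(
        st.floats(-5, 5),
        st.floats(-5, 5),
        st.floats(0.1, 3.0),
        st.floats(0, 2 * np.pi),
    )
    @settings(max_examples=20, deadline=None)
    def test_circle_center_transforms(self, tx, ty, scale, theta):
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.c_[2 + np.cos(ang), -1 + np.sin(ang)]
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = scale * (pts @ rot.T) + (tx, ty)
        fit = fit_circle(moved)
        expect = scale * (rot @ np.array([2.0, -1.0])) + (tx, ty)
        assert fit.center == pytest.approx(tuple(expect), abs=1e-6)
        assert fit.radius == pytest.approx(scale, abs=1e-6)

    def test_normalized_pupil_invariant_under_translation_scale(self):
        x = np.linspace(-2, 2, 9)
        top, bottom = np.c_[x, -(x**2) + 2], np.c_[x, x**2]
        pupil = np.array([0.4, 1.0])
        base = normalize_pupil(pupil, fit_eye_geometry(top, bottom))
        for scale, shift in ((2.0, (3.0, -1.0)), (0.5, (-2.0, 4.0))):
            # scaling x by s scales parabola coefficients; refit from moved points
            geom = fit_eye_geometry(scale * top + shift, scale * bottom + shift)
            moved = normalize_pupil(scale * pupil + shift, geom)
            assert moved == pytest.approx(base, abs=1e-9)
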