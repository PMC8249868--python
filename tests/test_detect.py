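"""Pupil detection, ellipse fitting, and fit-confidence metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereopupil import detect as det
from stereopupil import synthetic as syn
from stereopupil.errors import DegenerateInputError, InvalidFitError

GRAYS = {"pupil": 30, "iris": 140, "sclera": 200}


def _sample_ellipse(center, a, b, theta_deg, n=40):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    th = math.radians(theta_deg)
    x = center[0] + a * np.cos(t) * math.cos(th) - b * np.sin(t) * math.sin(th)
    y = center[1] + a * np.cos(t) * math.sin(th) + b * np.sin(t) * math.cos(th)
    return np.column_stack([x, y])


class TestFitEllipse:
    def test_circle_is_recovered_rotation_invariantly(self):
        t = np.linspace(0, 2 * math.pi, 8, endpoint=False)
        pts = np.column_stack([10 + 5 * np.cos(t), 10 + 5 * np.sin(t)])
        (cx, cy), a, b, _ = det.fit_ellipse(pts)
        assert cx == pytest.approx(10, abs=1e-9)
        assert cy == pytest.approx(10, abs=1e-9)
        assert a == pytest.approx(5, abs=1e-9)
        assert b == pytest.approx(5, abs=1e-9)

    def test_exact_parameter_recovery(self):
        pts = _sample_ellipse((0, 0), 4, 2, 30)
        (cx, cy), a, b, theta = det.fit_ellipse(pts)
        assert abs(cx) < 1e-6 and abs(cy) < 1e-6
        assert a == pytest.approx(4, abs=1e-6)
        assert b == pytest.approx(2, abs=1e-6)
        assert theta == pytest.approx(30, abs=1e-6)

    def test_collinear_points_are_degenerate(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(DegenerateInputError):
            det.fit_ellipse(pts)

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            det.fit_ellipse([(0, 0), (1, 1), (2, 0), (1, -1)])

    @settings(max_examples=30, derandomize=True)
    @given(
        a=st.floats(3, 50),
        ratio=st.floats(0.3, 1.0),
        theta=st.floats(0, 179.0),
        cx=st.floats(-30, 30),
        cy=st.floats(-30, 30),
    )
    def test_random_ellipses_recovered_with_normalized_angle(
        self, a, ratio, theta, cx, cy
    ):
        b = a * ratio
        pts = _sample_ellipse((cx, cy), a, b, theta)
        (fx, fy), fa, fb, ftheta = det.fit_ellipse(pts)
        assert 0 <= ftheta < 180
        assert fa >= fb > 0
        assert fa == pytest.approx(a, rel=1e-5)
        assert fb == pytest.approx(b, rel=1e-5)
        assert fx == pytest.approx(cx, abs=1e-5)
        assert fy == pytest.approx(cy, abs=1e-5)


class TestDetectPupil:
    def test_known_ellipse_recovered(self):
        truth = det.PupilFit(center=(256.0, 250.0), major_axis=120.0,
                             minor_axis=110.0, angle=20.0, valid=True)
        img = syn.render_eye_image(truth, GRAYS, 0.0, 0, (512, 512))
        fit = det.detect_pupil(img)
        assert fit.valid
        assert np.hypot(fit.center[0] - 256, fit.center[1] - 250) < 0.5
        assert fit.major_axis == pytest.approx(120, rel=0.02)
        assert fit.minor_axis == pytest.approx(110, rel=0.02)
        assert fit.angle == pytest.approx(20, abs=2)
        assert fit.outline_confidence == 1.0

    def test_uniform_image_is_invalid(self):
        img = det.EyeImage(np.full((200, 200), 128, dtype=np.uint8))
        fit = det.detect_pupil(img)
        assert not fit.valid
        assert fit.outline_confidence == 0.0

    def test_malformed_image_raises(self):
        with pytest.raises(ValueError):
            det.EyeImage(np.zeros((0, 10)))
        with pytest.raises(ValueError):
            det.EyeImage(np.zeros(10))

    def test_clean_batch_has_zero_invalid_rate(self):
        """200 clean rendered frames must all yield valid fits."""
        rng = np.random.default_rng(0)
        n_valid = 0
        for i in range(200):
            a = rng.uniform(50, 90)
            truth = det.PupilFit(
                center=(128 + rng.uniform(-10, 10), 128 + rng.uniform(-10, 10)),
                major_axis=a, minor_axis=a * rng.uniform(0.85, 1.0),
                angle=rng.uniform(0, 180), valid=True,
            )
            img = syn.render_eye_image(truth, GRAYS, 2.0, i, (256, 256))
            n_valid += det.detect_pupil(img).valid
        assert n_valid == 200

    @pytest.mark.parametrize("shift", [(1, 0), (0, 1), (5, -3), (-7, 4)])
    def test_translation_equivariance(self, shift):
        dx, dy = shift
        base = det.PupilFit(center=(200.0, 200.0), major_axis=100.0,
                            minor_axis=92.0, angle=70.0, valid=True)
        moved = det.PupilFit(center=(200.0 + dx, 200.0 + dy), major_axis=100.0,
                             minor_axis=92.0, angle=70.0, valid=True)
        f0 = det.detect_pupil(syn.render_eye_image(base, GRAYS, 0.0, 0, (400, 400)))
        f1 = det.detect_pupil(syn.render_eye_image(moved, GRAYS, 0.0, 0, (400, 400)))
        assert f1.center[0] - f0.center[0] == pytest.approx(dx, abs=0.1)
        assert f1.center[1] - f0.center[1] == pytest.approx(dy, abs=0.1)

    def test_roi_detection_matches_full_frame(self):
        truth = det.PupilFit(center=(256.0, 250.0), major_axis=120.0,
                             minor_axis=110.0, angle=20.0, valid=True)
        img = syn.render_eye_image(truth, GRAYS, 0.0, 0, (512, 512))
        full = det.detect_pupil(img)
        roi = det.detect_pupil(img, det.DetectorParams(roi=(150, 140, 220, 220)))
        assert roi.valid
        assert abs(roi.center[0] - full.center[0]) < 0.1
        assert abs(roi.center[1] - full.center[1]) < 0.1
        assert roi.major_axis == pytest.approx(full.major_axis, rel=0.005)
        assert roi.minor_axis == pytest.approx(full.minor_axis, rel=0.005)

    def test_roi_outside_image_raises(self):
        img = det.EyeImage(np.full((100, 100), 128, dtype=np.uint8))
        with pytest.raises(ValueError):
            det.detect_pupil(img, det.DetectorParams(roi=(50, 50, 100, 100)))

    @pytest.mark.parametrize("a", [40, 80, 160, 240, 300])
    def test_noiseless_axis_recovery_below_one_percent(self, a):
        b = 0.92 * a
        size = int(math.ceil(2.6 * a))
        truth = det.PupilFit(center=(size / 2, size / 2), major_axis=float(a),
                             minor_axis=b, angle=35.0, valid=True)
        img = syn.render_eye_image(truth, GRAYS, 0.0, 0, (size, size))
        fit = det.detect_pupil(img)
        assert fit.valid
        assert abs(fit.major_axis - a) / a < 0.01
        assert abs(fit.minor_axis - b) / b < 0.01


class TestConfidenceMetrics:
    def test_outline_confidence_saturates_on_high_contrast(self):
        fit = det.PupilFit(center=(100.0, 100.0), major_axis=80.0,
                           minor_axis=80.0, angle=0.0, valid=True)
        img = syn.render_eye_image(fit, {"pupil": 20, "iris": 200, "sclera": 200},
                                   0.0, 0, (200, 200))
        assert det.outline_confidence(img, fit, band_px=3, t_sat=25) == 1.0

    def test_outline_confidence_zero_on_uniform(self):
        fit = det.PupilFit(center=(100.0, 100.0), major_axis=80.0,
                           minor_axis=80.0, angle=0.0, valid=True)
        img = np.full((200, 200), 128, dtype=np.uint8)
        assert det.outline_confidence(img, fit, band_px=3) == 0.0

    def test_outline_confidence_half_at_half_saturation(self):
        """A constructed 12.5-gray-level edge scores 0.5 with T_sat = 25."""
        fit = det.PupilFit(center=(100.0, 100.0), major_axis=80.0,
                           minor_axis=80.0, angle=0.0, valid=True)
        yy, xx = np.mgrid[0:200, 0:200]
        inside = np.hypot(xx - 100, yy - 100) <= 40
        img = np.where(inside, 100.0, 112.5)
        score = det.outline_confidence(img, fit, band_px=3, t_sat=25)
        assert score == pytest.approx(0.5, abs=0.01)

    def test_outline_confidence_monotone_in_contrast(self):
        fit = det.PupilFit(center=(100.0, 100.0), major_axis=80.0,
                           minor_axis=80.0, angle=0.0, valid=True)
        yy, xx = np.mgrid[0:200, 0:200]
        inside = np.hypot(xx - 100, yy - 100) <= 40
        scores = []
        for contrast in [0, 5, 10, 15, 20, 30]:
            img = np.where(inside, 100.0, 100.0 + contrast)
            scores.append(det.outline_confidence(img, fit, band_px=3, t_sat=25))
        assert all(s1 <= s2 + 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_invalid_fit_scores_zero_with_warning(self):
        img = np.full((50, 50), 128, dtype=np.uint8)
        with pytest.warns(UserWarning):
            assert det.outline_confidence(img, det.PupilFit.invalid()) == 0.0

    @pytest.mark.parametrize(
        "a,b,expected", [(10, 10, 1.0), (10, 5, 0.5), (120, 114, 0.95)]
    )
    def test_axis_ratio(self, a, b, expected):
        fit = det.PupilFit(center=(0, 0), major_axis=a, minor_axis=b,
                           angle=0.0, valid=True)
        assert det.axis_ratio(fit) == pytest.approx(expected)

    def test_axis_ratio_invalid_fit_raises(self):
        with pytest.raises(InvalidFitError):
            det.axis_ratio(det.PupilFit.invalid())

    def test_angular_edge_spread(self):
        fit = det.PupilFit(center=(0.0, 0.0), major_axis=10.0, minor_axis=10.0,
                           angle=0.0, valid=True)
        full = _sample_ellipse((0, 0), 5, 5, 0, n=36)  # every 10 degrees
        assert det.angular_edge_spread(full, fit, 8) == 1.0
        one_sector = np.column_stack(
            [5 * np.cos(np.linspace(0.1, 0.6, 10)),
             5 * np.sin(np.linspace(0.1, 0.6, 10))]
        )
        assert det.angular_edge_spread(one_sector, fit, 8) == 0.125
        cross = np.array([(5, 0), (0, 5), (-5, 0), (0, -5)], dtype=float)
        assert det.angular_edge_spread(cross, fit, 8) == 0.5
        assert det.angular_edge_spread(np.empty((0, 2)), fit, 8) == 0.0

    @pytest.mark.parametrize(
        "inputs,expected", [((1, 1, 1), 1.0), ((0, 0, 0), 0.0), ((1.0, 0.9, 0.5), 0.8)]
    )
    def test_general_confidence_is_mean(self, inputs, expected):
        assert det.general_confidence(*inputs) == pytest.approx(expected)

    def test_general_confidence_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            det.general_confidence(1.2, 0.5, 0.5)


class TestDetectorInterface:
    def test_threshold_detector_implements_contract(self):
        d = det.ThresholdPupilDetector()
        assert not d.has_confidence()
        truth = det.PupilFit(center=(128.0, 128.0), major_axis=80.0,
                             minor_axis=76.0, angle=0.0, valid=True)
        img = syn.render_eye_image(truth, GRAYS, 0.0, 0, (256, 256))
        fit = d.run(img)
        assert fit.valid and fit.algorithm_confidence is None

    def test_circumference_matches_ramanujan(self):
        fit = det.PupilFit(center=(0, 0), major_axis=10.0, minor_axis=10.0,
                           angle=0.0, valid=True)
        assert fit.circumference_px == pytest.approx(math.pi * 10.0, rel=1e-9)
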