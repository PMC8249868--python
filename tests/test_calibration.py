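"""Camera calibration: parameter recovery, error metrics, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from stereopupil import calibration as cal
from stereopupil import geometry as geo
from stereopupil import synthetic as syn
from stereopupil.errors import ConditioningError, InsufficientViewsError


class TestDistortionModel:
    @settings(max_examples=30, derandomize=True)
    @given(
        x=st.floats(-0.45, 0.45), y=st.floats(-0.45, 0.45),
        k1=st.floats(-0.2, 0.2), k2=st.floats(-0.05, 0.05),
        p1=st.floats(-0.005, 0.005), p2=st.floats(-0.005, 0.005),
    )
    def test_distort_undistort_roundtrip(self, x, y, k1, k2, p1, p2):
        dist = np.array([k1, k2, p1, p2, 0.0])
        xy = np.array([[x, y]])
        there = geo.distort_normalized(xy, dist)
        back = geo.undistort_normalized(there, dist)
        assert np.abs(back - xy).max() < 1e-6
        fwd = geo.distort_normalized(geo.undistort_normalized(xy, dist), dist)
        assert np.abs(fwd - xy).max() < 1e-6

    def test_zero_coefficients_are_identity(self):
        xy = np.array([[0.3, -0.2], [0.0, 0.0]])
        zero = np.zeros(5)
        assert np.array_equal(geo.distort_normalized(xy, zero), xy)
        assert np.array_equal(geo.undistort_normalized(xy, zero), xy)


class TestIntrinsics:
    def test_noiseless_recovery_within_tenth_percent(self, reference_cfg, pattern):
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=10, corner_px_sd=0.0, seed=3,
            stereo=False,
        )
        intr = cal.calibrate_intrinsics(
            views.main, pattern, reference_cfg.rig.image_size,
            estimate_distortion=False,
        )
        assert abs(intr.fx - 14493) / 14493 < 1e-3
        assert abs(intr.fy - 14493) / 14493 < 1e-3
        assert abs(intr.cx - 1023.5) < 1.0
        assert abs(intr.cy - 767.5) < 1.0
        assert intr.rmse_px < 1e-8

    def test_noise_floor_sets_rmse(self, reference_cfg, pattern):
        """Residual RMSE matches the injected corner noise asymptotically."""
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=30, corner_px_sd=0.1, seed=42,
            stereo=False,
        )
        intr = cal.calibrate_intrinsics(
            views.main, pattern, reference_cfg.rig.image_size
        )
        noise_rms = 0.1 * np.sqrt(2)  # per-point Euclidean RMS of the noise
        assert noise_rms / 2 < intr.rmse_px < noise_rms * 2

    def test_two_views_underdetermined(self, reference_cfg, pattern):
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=3, corner_px_sd=0.0, seed=1,
            stereo=False,
        )
        with pytest.raises(ConditioningError):
            cal.calibrate_intrinsics(
                views.main[:2], pattern, reference_cfg.rig.image_size
            )


class TestReprojectionErrors:
    def test_perfect_parameters_give_zero(self, reference_cfg, pattern):
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=3, corner_px_sd=0.0, seed=8,
            stereo=False,
        )
        rig = syn.build_rig(reference_cfg.rig)
        extr = [cal.CameraExtrinsics(R, T) for R, T in views.poses]
        rmse, mae = cal.reprojection_errors(views.true_main, pattern, rig.main, extr)
        assert rmse < 1e-9 and mae < 1e-9

    def test_hand_computed_two_point_errors(self):
        """Distances {3 px, 4 px} give RMSE sqrt(12.5) and MAE 3.5."""
        tiny = cal.CalibrationPattern(cols=2, rows=1, square_size=10.0)
        intr = cal.CameraIntrinsics(fx=1000, fy=1000, cx=320, cy=240,
                                    image_size=(640, 480))
        ext = cal.CameraExtrinsics(np.eye(3), np.array([0.0, 0.0, 500.0]))
        ideal = geo.project_points(tiny.ideal_corners, ext.R, ext.T, intr.K)
        observed = ideal + np.array([[3.0, 0.0], [0.0, 4.0]])
        rmse, mae = cal.reprojection_errors([observed], tiny, intr, [ext])
        assert rmse == pytest.approx(np.sqrt(12.5), rel=1e-12)
        assert mae == pytest.approx(3.5, rel=1e-12)

    def test_gaussian_noise_mae_rmse_is_rayleigh_ratio(self, reference_cfg, pattern):
        """Isotropic corner noise gives MAE/RMSE -> sqrt(pi)/2 ~ 0.886."""
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=30, corner_px_sd=0.1, seed=9,
            stereo=False,
        )
        rig = syn.build_rig(reference_cfg.rig)
        extr = [cal.CameraExtrinsics(R, T) for R, T in views.poses]
        rmse, mae = cal.reprojection_errors(views.main, pattern, rig.main, extr)
        assert mae / rmse == pytest.approx(np.sqrt(np.pi) / 2, abs=0.03)

    def test_mismatched_counts_raise(self, reference_cfg, pattern):
        rig = syn.build_rig(reference_cfg.rig)
        with pytest.raises(ValueError):
            cal.reprojection_errors(
                [np.zeros((5, 2))], pattern, rig.main,
                [cal.CameraExtrinsics(np.eye(3), np.array([0, 0, 1.0]))],
            )


class TestVerification:
    def test_heldout_noiseless_mae_is_zero(self, reference_cfg, pattern):
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=5, corner_px_sd=0.0, seed=21,
            stereo=False,
        )
        rig = syn.build_rig(reference_cfg.rig)
        assert cal.verify_calibration(views.main, pattern, rig.main) < 1e-6

    def test_heldout_noise_mae_in_rayleigh_band(self, reference_cfg, pattern):
        """Corner noise SD 0.05 px gives a held-out MAE near its Rayleigh
        mean 0.063 px (within [0.03, 0.07])."""
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=10, corner_px_sd=0.05, seed=22,
            stereo=False,
        )
        rig = syn.build_rig(reference_cfg.rig)
        mae = cal.verify_calibration(views.main, pattern, rig.main)
        assert 0.03 <= mae <= 0.07

    def test_verification_mae_exceeds_in_sample_mae_on_average(
        self, reference_cfg, pattern
    ):
        diffs = []
        for seed in range(4):
            views = syn.generate_pattern_views(
                reference_cfg, pattern, n_views=20, corner_px_sd=0.1,
                seed=100 + seed, stereo=False,
            )
            intr = cal.calibrate_intrinsics(
                views.main[:10], pattern, reference_cfg.rig.image_size,
                estimate_distortion=False,
            )
            verify = cal.verify_calibration(views.main[10:], pattern, intr)
            diffs.append(verify - intr.mae_px)
        assert np.mean(diffs) >= 0.0

    def test_no_views_raise(self, pattern, reference_rig):
        with pytest.raises(InsufficientViewsError):
            cal.verify_calibration([], pattern, reference_rig.main)


class TestStereo:
    def test_noiseless_extrinsic_recovery(self, reference_cfg, pattern, stereo_views):
        im = cal.calibrate_intrinsics(
            stereo_views.main, pattern, reference_cfg.rig.image_size,
            estimate_distortion=False,
        )
        isec = cal.calibrate_intrinsics(
            stereo_views.secondary, pattern, reference_cfg.rig.image_size,
            estimate_distortion=False,
        )
        rig = cal.calibrate_stereo(
            stereo_views.main, stereo_views.secondary, pattern, im, isec
        )
        assert np.linalg.norm(rig.T) == pytest.approx(75.0, rel=1e-3)
        angle = np.degrees(
            np.linalg.norm(Rotation.from_matrix(rig.R).as_rotvec())
        )
        assert angle == pytest.approx(8.0, rel=1e-3)

    def test_identical_cameras_give_identity_pose(self, reference_cfg, pattern):
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=6, corner_px_sd=0.0, seed=31,
            stereo=False,
        )
        rig = syn.build_rig(reference_cfg.rig)
        stereo = cal.calibrate_stereo(
            views.main, views.main, pattern, rig.main, rig.main
        )
        assert np.allclose(stereo.R, np.eye(3), atol=1e-8)
        assert np.allclose(stereo.T, 0.0, atol=1e-6)

    def test_unpaired_views_raise(self, reference_cfg, pattern, stereo_views):
        rig = syn.build_rig(reference_cfg.rig)
        with pytest.raises(ValueError):
            cal.calibrate_stereo(
                stereo_views.main[:3], stereo_views.secondary[:2], pattern,
                rig.main, rig.secondary,
            )

    def test_pattern_size_error_noiseless(self, pattern, reference_rig, stereo_views):
        err = cal.pattern_size_error(
            reference_rig,
            list(zip(stereo_views.true_main, stereo_views.true_secondary)),
            pattern,
        )
        assert err < 1e-6

    def test_pattern_size_error_scales_with_scene(self, reference_cfg, pattern):
        """Scaling the whole scene (squares + rig) doubles the deviations
        under fixed pixel noise: triangulation is scale-linear."""
        views = syn.generate_pattern_views(
            reference_cfg, pattern, n_views=6, corner_px_sd=0.02, seed=55,
            stereo=True,
        )
        rig = syn.build_rig(reference_cfg.rig)
        err1 = cal.pattern_size_error(
            rig, list(zip(views.main, views.secondary)), pattern
        )
        rig2 = cal.StereoRig(main=rig.main, secondary=rig.secondary,
                             R=rig.R, T=2.0 * rig.T)
        pattern2 = cal.CalibrationPattern(
            cols=pattern.cols, rows=pattern.rows,
            square_size=2.0 * pattern.square_size,
        )
        err2 = cal.pattern_size_error(
            rig2, list(zip(views.main, views.secondary)), pattern2
        )
        assert err2 == pytest.approx(2.0 * err1, rel=1e-9)


class TestCollection:
    def test_collects_exact_count_skipping_blanks(self, small_cfg, pattern):
        stream = syn.pattern_image_stream(
            small_cfg, pattern, n_views=5, seed=2, blank_every=2
        )
        views = cal.collect_pattern_views(stream, pattern, n_images=5)
        assert len(views) == 5
        assert all(v.shape == (pattern.n_corners, 2) for v in views)

    def test_detected_corners_match_projection(self, small_cfg, pattern):
        views = cal.collect_pattern_views(
            syn.pattern_image_stream(small_cfg, pattern, n_views=3, seed=2),
            pattern, n_images=3,
        )
        truth = syn.generate_pattern_views(
            small_cfg, pattern, n_views=3, corner_px_sd=0.0, seed=2, stereo=False
        )
        for detected, true in zip(views, truth.true_main):
            err = min(
                np.linalg.norm(detected - true, axis=1).mean(),
                np.linalg.norm(detected[::-1] - true, axis=1).mean(),
            )
            assert err < 0.5

    def test_exhausted_stream_raises(self, small_cfg, pattern):
        stream = syn.pattern_image_stream(small_cfg, pattern, n_views=3, seed=2)
        with pytest.raises(InsufficientViewsError):
            cal.collect_pattern_views(stream, pattern, n_images=30)


class TestPersistence:
    def test_yaml_roundtrip_is_bit_exact(self, tmp_path, reference_rig, pattern):
        reference_rig.stereo_rmse_px = 0.123456789012345678
        reference_rig.pattern_error_mm = 1.5e-3
        path = tmp_path / "calib.yaml"
        cal.save_calibration(reference_rig, pattern, path)
        rig2, pattern2 = cal.load_calibration(path)
        assert rig2.main.fx == reference_rig.main.fx
        assert np.array_equal(rig2.R, reference_rig.R)
        assert np.array_equal(rig2.T, reference_rig.T)
        assert rig2.stereo_rmse_px == reference_rig.stereo_rmse_px
        assert pattern2.square_size == pattern.square_size
        path2 = tmp_path / "calib2.yaml"
        cal.save_calibration(rig2, pattern2, path2)
        rig3, _ = cal.load_calibration(path2)
        assert rig3.main.fx == rig2.main.fx
        assert np.array_equal(rig3.R, rig2.R)

    def test_extrinsics_validate_rotation(self):
        with pytest.raises(ValueError):
            cal.CameraExtrinsics(np.eye(3) * 2.0, np.zeros(3))
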