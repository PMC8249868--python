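"""Absolute pupil diameter from calibrated stereo pupil fits.

The endpoints of the fitted ellipse's major axis are extracted in both
images, undistorted, triangulated into world coordinates (linear DLT
least squares, homogeneous result converted to Cartesian with
``omega = W_H`` when nonzero, else 1), and the absolute diameter is the
Euclidean distance between the two world points (mm).
"""

from __future__ import annotations

import math

import numpy as np

from . import geometry as geo
from .calibration import StereoRig
from .detect import EyeImage, PupilFit
from .errors import (
    CalibrationStateError,
    InvalidFitError,
    StreamCorruptionError,
    TriangulationDegenerateError,
)

#: rays closer to parallel than this angle (radians) are rejected
MIN_RAY_ANGLE_RAD = 1e-8


def major_axis_endpoints(fit: PupilFit) -> np.ndarray:
    """The two px endpoints of the major axis: ``center +/- (a/2) u``.

    ``u = (cos theta, sin theta)``; these are the midpoints of the short
    sides of the ellipse's minimal encompassing rectangle.  Returned in a
    canonical order (the ``+u`` endpoint last), which keeps the
    cross-camera correspondence stable for a rig without relative roll.
    """
    if not fit.valid:
        raise InvalidFitError("endpoints are undefined for an invalid fit")
    th = math.radians(fit.angle)
    u = np.array([math.cos(th), math.sin(th)])
    c = np.asarray(fit.center, dtype=float)
    half = 0.5 * fit.major_axis
    return np.vstack([c - half * u, c + half * u])


def home2cart(p: np.ndarray) -> np.ndarray:
    """Homogeneous ``(X_H, Y_H, Z_H, W_H)`` to Cartesian world coordinates.

    The scale is ``omega = W_H`` when ``W_H != 0`` and 1 otherwise, so
    points at infinity pass through unchanged instead of raising.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 4:
        raise ValueError("homogeneous points have 4 components")
    if not np.any(p):
        raise ValueError("the zero 4-vector is not a homogeneous point")
    w = p[..., 3]
    omega = np.where(w != 0.0, w, 1.0)
    return p[..., :3] / np.expand_dims(omega, -1)


def triangulate(p_main, p_secondary, rig: StereoRig) -> np.ndarray:
    """World point (mm, main-camera frame) of one stereo correspondence.

    Inputs are raw (distorted) pixel coordinates; they are undistorted with
    each camera's coefficients before the DLT intersection of the two
    projection rays through ``M1``/``M2``.
    """
    if rig is None:
        raise CalibrationStateError("a calibrated stereo rig is required")
    x1 = rig.main.undistort_points(np.atleast_2d(np.asarray(p_main, dtype=float)))
    x2 = rig.secondary.undistort_points(
        np.atleast_2d(np.asarray(p_secondary, dtype=float))
    )
    _check_ray_angle(x1, x2, rig)
    PH = geo.triangulate_dlt(rig.M1, rig.M2, x1, x2)
    P = home2cart(PH)
    return P[0] if np.asarray(p_main).ndim == 1 else P


def _check_ray_angle(x1: np.ndarray, x2: np.ndarray, rig: StereoRig) -> None:
    d1 = np.column_stack([geo.pixels_to_normalized(x1, rig.main.K), np.ones(len(x1))])
    d2n = np.column_stack(
        [geo.pixels_to_normalized(x2, rig.secondary.K), np.ones(len(x2))]
    )
    d2 = d2n @ rig.R  # R^T applied row-wise: secondary ray in main frame
    cosang = np.sum(d1 * d2, axis=1) / (
        np.linalg.norm(d1, axis=1) * np.linalg.norm(d2, axis=1)
    )
    ang = np.arccos(np.clip(np.abs(cosang), -1.0, 1.0))
    baseline = np.linalg.norm(rig.T)
    if baseline == 0.0 or np.any(ang < MIN_RAY_ANGLE_RAD):
        raise TriangulationDegenerateError(
            "projection rays are near-parallel; triangulation is unstable"
        )


def chord_endpoints(fit: PupilFit, direction_deg: float) -> np.ndarray:
    """Endpoints of the centre chord of a fitted ellipse along a direction.

    Along the fit's own major-axis angle this equals
    :func:`major_axis_endpoints`; it lets both cameras extract endpoints
    along one shared direction.
    """
    if not fit.valid:
        raise InvalidFitError("endpoints are undefined for an invalid fit")
    th = math.radians(direction_deg)
    u = np.array([math.cos(th), math.sin(th)])
    phi = math.radians(fit.angle)
    ux = u[0] * math.cos(phi) + u[1] * math.sin(phi)
    uy = -u[0] * math.sin(phi) + u[1] * math.cos(phi)
    A, B = fit.major_axis / 2.0, fit.minor_axis / 2.0
    half = 1.0 / math.sqrt((ux / A) ** 2 + (uy / B) ** 2)
    c = np.asarray(fit.center, dtype=float)
    return np.vstack([c - half * u, c + half * u])


def absolute_diameter(
    fit_main: PupilFit, fit_secondary: PupilFit, rig: StereoRig
) -> float | None:
    """Absolute pupil diameter in mm, or None when either fit is invalid.

    The major-axis endpoint pairs are triangulated and the diameter is the
    Euclidean distance of the two world points.  The endpoint direction is
    taken from the more elliptical of the two fits: a near-circular fit has
    a noise-driven axis angle, and mismatched endpoint directions across the
    cameras send the triangulated rays past each other.  For distinctly
    elliptical fits this direction is each fit's own major axis (the rig
    carries no relative roll), so the extracted points are the
    major-axis endpoint pairs.  No reliability threshold is applied here;
    artifact screening belongs to the pre-processing stage.
    """
    if not (fit_main.valid and fit_secondary.valid):
        return None
    ratio_main = fit_main.minor_axis / fit_main.major_axis
    ratio_sec = fit_secondary.minor_axis / fit_secondary.major_axis
    direction = fit_main.angle if ratio_main <= ratio_sec else fit_secondary.angle
    e1 = chord_endpoints(fit_main, direction)
    e2 = chord_endpoints(fit_secondary, direction)
    P = triangulate(e1, e2, rig)
    return float(np.linalg.norm(P[0] - P[1]))


def pair_frames(stream_main, stream_secondary):
    """Pair stereo frames by hardware frame count.

    Frame counts — not timestamps — identify simultaneity; unmatched counts
    are dropped.  Returns ``(pairs, n_dropped)`` with pairs ordered by frame
    count.  Duplicated counts within one stream raise
    :class:`StreamCorruptionError`.
    """
    def _index(stream, name):
        idx: dict[int, EyeImage] = {}
        for img in stream:
            fc = img.frame_count
            if fc in idx:
                raise StreamCorruptionError(
                    f"duplicate frame_count {fc} in {name} stream"
                )
            idx[fc] = img
        return idx

    main_idx = _index(stream_main, "main")
    sec_idx = _index(stream_secondary, "secondary")
    common = sorted(main_idx.keys() & sec_idx.keys())
    dropped = len(main_idx) + len(sec_idx) - 2 * len(common)
    return [(main_idx[fc], sec_idx[fc]) for fc in common], dropped


def measure_stereo_frame(
    image_main: EyeImage, image_secondary: EyeImage, detector, rig: StereoRig
) -> tuple[PupilFit, PupilFit, float | None]:
    """Run detection on one stereo pair and triangulate the diameter."""
    fm = detector.run(image_main)
    fs = detector.run(image_secondary)
    return fm, fs, absolute_diameter(fm, fs, rig)
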