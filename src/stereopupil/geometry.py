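"""Pinhole-camera geometry primitives.

Projection model: a world point ``X`` (mm) is mapped to camera coordinates
``Xc = R @ X + T``, normalised to ``(x, y) = (Xc/Zc, Yc/Zc)``, distorted with
the standard radial/tangential (Brown-Conrady) model with coefficients
``C = (k1, k2, p1, p2, k3)`` and finally scaled to pixels through the
intrinsic matrix ``K``.  All pixel quantities use a top-left, 0-based,
x-right / y-down image frame and are sub-pixel valued.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def rotvec_to_matrix(rvec: np.ndarray) -> np.ndarray:
    """Axis-angle (Rodrigues) vector to a 3x3 rotation matrix."""
    return Rotation.from_rotvec(np.asarray(rvec, dtype=float)).as_matrix()


def matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec()


def intrinsic_matrix(fx: float, fy: float, cx: float, cy: float) -> np.ndarray:
    return np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])


def distort_normalized(xy: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply radial + tangential distortion to normalised image coordinates.

    Parameters
    ----------
    xy : (N, 2) array of ideal (undistorted) normalised coordinates.
    dist : (5,) array ``(k1, k2, p1, p2, k3)``.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    k1, k2, p1, p2, k3 = np.asarray(dist, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.column_stack([xd, yd])


def undistort_normalized(
    xyd: np.ndarray,
    dist: np.ndarray,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> np.ndarray:
    """Invert :func:`distort_normalized` by fixed-point iteration.

    Converges to ``tol`` (normalised units) well inside the usable field for
    moderate distortion; with all-zero coefficients it is the identity map.
    """
    xyd = np.atleast_2d(np.asarray(xyd, dtype=float))
    k1, k2, p1, p2, k3 = np.asarray(dist, dtype=float)
    if not np.any([k1, k2, p1, p2, k3]):
        return xyd.copy()
    xy = xyd.copy()
    for _ in range(max_iter):
        x, y = xy[:, 0], xy[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        dx = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        xy_new = (xyd - np.column_stack([dx, dy])) / radial[:, None]
        if np.max(np.abs(xy_new - xy)) < tol:
            xy = xy_new
            break
        xy = xy_new
    return xy


def pixels_to_normalized(px: np.ndarray, K: np.ndarray) -> np.ndarray:
    px = np.atleast_2d(np.asarray(px, dtype=float))
    return np.column_stack(
        [(px[:, 0] - K[0, 2]) / K[0, 0], (px[:, 1] - K[1, 2]) / K[1, 1]]
    )


def normalized_to_pixels(xy: np.ndarray, K: np.ndarray) -> np.ndarray:
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    return np.column_stack(
        [xy[:, 0] * K[0, 0] + K[0, 2], xy[:, 1] * K[1, 1] + K[1, 2]]
    )


def project_points(
    world: np.ndarray,
    R: np.ndarray,
    T: np.ndarray,
    K: np.ndarray,
    dist: np.ndarray | None = None,
) -> np.ndarray:
    """Project (N, 3) world points to (N, 2) pixel coordinates."""
    world = np.atleast_2d(np.asarray(world, dtype=float))
    Xc = world @ np.asarray(R, dtype=float).T + np.asarray(T, dtype=float).ravel()
    if np.any(Xc[:, 2] <= 0):
        raise ValueError("points behind the camera cannot be projected")
    xy = Xc[:, :2] / Xc[:, 2:3]
    if dist is not None:
        xy = distort_normalized(xy, dist)
    return normalized_to_pixels(xy, K)


def undistort_pixels(px: np.ndarray, K: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Map raw (distorted) pixels to ideal pinhole pixels under the same K."""
    return normalized_to_pixels(undistort_normalized(pixels_to_normalized(px, K), dist), K)


def homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Planar homography ``dst ~ H @ src`` by the normalised DLT.

    ``src`` and ``dst`` are (N, 2) point sets, N >= 4.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape[0] < 4:
        raise ValueError("homography needs at least 4 correspondences")

    def _normalise(pts):
        mean = pts.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - mean, axis=1)), 1e-12)
        T = np.array(
            [[scale, 0, -scale * mean[0]], [0, scale, -scale * mean[1]], [0, 0, 1]]
        )
        return (pts - mean) * scale, T

    s, Ts = _normalise(src)
    d, Td = _normalise(dst)
    n = s.shape[0]
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = s
    A[0::2, 2] = 1.0
    A[0::2, 6:8] = -d[:, 0:1] * s
    A[0::2, 8] = -d[:, 0]
    A[1::2, 3:5] = s
    A[1::2, 5] = 1.0
    A[1::2, 6:8] = -d[:, 1:2] * s
    A[1::2, 8] = -d[:, 1]
    _, _, Vt = np.linalg.svd(A)
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return H / H[2, 2]


def triangulate_dlt(
    M1: np.ndarray, M2: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> np.ndarray:
    """Linear (DLT) triangulation of corresponding ideal pixel points.

    ``x1``/``x2`` are (N, 2) undistorted pixel coordinates under projection
    matrices ``M1``/``M2``.  Returns (N, 4) homogeneous world points, each the
    least-squares ray intersection (smallest singular vector of the 4x4 DLT
    system).
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    n = x1.shape[0]
    A = np.empty((n, 4, 4))
    A[:, 0] = x1[:, 0:1] * M1[2] - M1[0]
    A[:, 1] = x1[:, 1:2] * M1[2] - M1[1]
    A[:, 2] = x2[:, 0:1] * M2[2] - M2[0]
    A[:, 3] = x2[:, 1:2] * M2[2] - M2[1]
    _, _, Vt = np.linalg.svd(A)
    return Vt[:, -1, :]


def pose_from_homography(H: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recover (R, T) of a Z=0 plane from its image homography and known K."""
    A = np.linalg.inv(K) @ H
    lam = 1.0 / np.linalg.norm(A[:, 0])
    r1 = lam * A[:, 0]
    r2 = lam * A[:, 1]
    t = lam * A[:, 2]
    if t[2] < 0:  # plane must sit in front of the camera
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    Q = np.column_stack([r1, r2, r3])
    # nearest proper rotation
    U, _, Vt = np.linalg.svd(Q)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R, t
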