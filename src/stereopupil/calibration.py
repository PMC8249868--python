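"""Single- and stereo-camera calibration with quality validation.

Intrinsics are estimated by Zhang's planar-target method: per-view
homographies give a closed-form initialisation, followed by a full bundle
refinement of ``(fx, fy, cx, cy, k1, k2, p1, p2, k3)`` and the per-view
poses that minimises the squared reprojection error.  Stereo calibration
fixes the intrinsics and refines the relative pose of the secondary camera
with respect to the main camera jointly with the per-view pattern poses.

Quality is reported as the per-point Euclidean RMSE and MAE reprojection
errors (px), plus an absolute-unit check: the triangulated size of the
calibration-pattern squares against their known size (mm).
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix
from scipy.spatial.transform import Rotation

from . import geometry as geo
from .errors import (
    CalibrationStateError,
    ConditioningError,
    InsufficientViewsError,
)

DEFAULT_N_VIEWS = 30
DEFAULT_COLLECTION_FPS = 0.5


@dataclass
class CalibrationPattern:
    """Planar chessboard target: inner-corner grid on the Z=0 plane."""

    cols: int = 9
    rows: int = 6
    square_size: float = 10.0  # mm

    @property
    def n_corners(self) -> int:
        return self.rows * self.cols

    @property
    def ideal_corners(self) -> np.ndarray:
        """(N, 3) world coordinates, row-major over the grid, Z = 0."""
        jj, ii = np.meshgrid(np.arange(self.cols), np.arange(self.rows))
        return np.column_stack(
            [jj.ravel() * self.square_size, ii.ravel() * self.square_size,
             np.zeros(self.n_corners)]
        )

    @property
    def grid(self) -> np.ndarray:
        return self.ideal_corners[:, :2]

    def adjacent_pairs(self) -> np.ndarray:
        """Index pairs of corners one square apart (along rows and columns)."""
        idx = np.arange(self.n_corners).reshape(self.rows, self.cols)
        horiz = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
        vert = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
        return np.vstack([horiz, vert])


@dataclass
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float
    dist: np.ndarray = field(default_factory=lambda: np.zeros(5))  # k1,k2,p1,p2,k3
    image_size: tuple[int, int] = (2048, 1536)  # (width, height)
    rmse_px: float | None = None
    mae_px: float | None = None

    def __post_init__(self):
        self.dist = np.asarray(self.dist, dtype=float).reshape(5)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return geo.intrinsic_matrix(self.fx, self.fy, self.cx, self.cy)

    def undistort_points(self, px: np.ndarray) -> np.ndarray:
        return geo.undistort_pixels(px, self.K, self.dist)

    def project(self, world: np.ndarray, R: np.ndarray, T: np.ndarray) -> np.ndarray:
        return geo.project_points(world, R, T, self.K, self.dist)


@dataclass
class CameraExtrinsics:
    """Rigid pose: camera coordinates are ``R @ X + T`` (T in mm)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-9):
            raise ValueError("R must be orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation (det = +1)")


@dataclass
class StereoRig:
    """Calibrated stereo pair; (R, T) pose the secondary w.r.t. the main."""

    main: CameraIntrinsics
    secondary: CameraIntrinsics
    R: np.ndarray
    T: np.ndarray
    stereo_rmse_px: float | None = None
    pattern_error_mm: float | None = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.T = np.asarray(self.T, dtype=float).reshape(3)

    @property
    def M1(self) -> np.ndarray:
        """Main-camera projection matrix ``K1 [I | 0]``."""
        return self.main.K @ np.hstack([np.eye(3), np.zeros((3, 1))])

    @property
    def M2(self) -> np.ndarray:
        """Secondary projection matrix ``K2 [R | T]``."""
        return self.secondary.K @ np.hstack([self.R, self.T.reshape(3, 1)])

    @property
    def baseline_mm(self) -> float:
        return float(np.linalg.norm(self.T))


# ---------------------------------------------------------------------------
# chessboard corner detection (image-based collection)
# ---------------------------------------------------------------------------

def find_chessboard_corners(image, pattern: CalibrationPattern) -> np.ndarray | None:
    """Locate and order the inner corners of a chessboard in an image.

    Harris corners are refined to sub-pixel accuracy and ordered row-major
    through a homography fitted from the grid's extreme corners.  Returns an
    (N, 2) array of (x, y) pixel coordinates, or None when no full corner
    grid is found.
    """
    from skimage.feature import corner_harris, corner_peaks, corner_subpix

    px = np.asarray(image.pixels if hasattr(image, "pixels") else image, dtype=float)
    n = pattern.n_corners
    response = corner_harris(px, sigma=2.5)
    peaks = corner_peaks(response, min_distance=7, num_peaks=n * 4,
                         threshold_rel=0.01)
    if peaks.shape[0] < n:
        return None
    peaks = peaks[_is_x_corner(px, peaks)]
    if peaks.shape[0] < n:
        return None
    strengths = response[peaks[:, 0], peaks[:, 1]]
    peaks = peaks[np.argsort(strengths)[::-1][:n]]
    refined = corner_subpix(px, peaks.astype(float), window_size=11)
    bad = ~np.isfinite(refined).all(axis=1)
    refined[bad] = peaks[bad]
    pts = refined[:, ::-1]  # (x, y)
    ordered = _order_grid(pts, pattern)
    return ordered


def _is_x_corner(px: np.ndarray, peaks: np.ndarray, radius: int = 4) -> np.ndarray:
    """Keep saddle (checkerboard X) corners; drop outer board L-corners.

    At an X-corner the two diagonal quadrant pairs agree internally and
    contrast strongly with each other; an L-corner has one odd quadrant.
    """
    h, w = px.shape
    keep = np.zeros(len(peaks), dtype=bool)
    for i, (r, c) in enumerate(peaks):
        if not (radius <= r < h - radius and radius <= c < w - radius):
            continue
        q1 = px[r - radius, c - radius]
        q2 = px[r - radius, c + radius]
        q3 = px[r + radius, c + radius]
        q4 = px[r + radius, c - radius]
        cross = abs((q1 + q3) / 2.0 - (q2 + q4) / 2.0)
        within = max(abs(q1 - q3), abs(q2 - q4))
        keep[i] = cross > 50.0 and within < 0.5 * cross
    return keep


def _order_grid(pts: np.ndarray, pattern: CalibrationPattern) -> np.ndarray | None:
    """Order scattered grid corners row-major via a 4-point homography."""
    from scipy.spatial import ConvexHull

    rows, cols = pattern.rows, pattern.cols
    try:
        hull = ConvexHull(pts)
    except Exception:
        return None
    hv = pts[hull.vertices]
    if hv.shape[0] < 4:
        return None
    # max-area quadrilateral on the hull = the four grid corners
    best_quad, best_area = None, -1.0
    for quad in itertools.combinations(range(hv.shape[0]), 4):
        q = hv[list(quad)]
        area = 0.5 * abs(
            np.dot(q[:, 0], np.roll(q[:, 1], -1)) - np.dot(q[:, 1], np.roll(q[:, 0], -1))
        )
        if area > best_area:
            best_area, best_quad = area, q
    corners_ideal = np.array(
        [[0.0, 0.0], [cols - 1.0, 0.0], [cols - 1.0, rows - 1.0], [0.0, rows - 1.0]]
    )
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    grid_nodes = np.column_stack([jj.ravel(), ii.ravel()]).astype(float)

    best_assign, best_cost = None, np.inf
    for start in range(4):
        for flip in (1, -1):
            quad = np.roll(best_quad[::flip], start, axis=0)
            try:
                H = geo.homography_dlt(corners_ideal, quad)
            except Exception:
                continue
            h = np.column_stack([grid_nodes, np.ones(len(grid_nodes))]) @ H.T
            pred = h[:, :2] / h[:, 2:3]
            d = np.linalg.norm(pred[:, None, :] - pts[None, :, :], axis=2)
            assign = np.argmin(d, axis=1)
            cost = d[np.arange(len(assign)), assign].sum()
            if len(np.unique(assign)) == len(assign) and cost < best_cost:
                best_cost, best_assign = cost, assign
    if best_assign is None:
        return None
    ordered = pts[best_assign]
    # canonical orientation: column index increases with image x, row index
    # with image y (consistent labelling across stereo cameras)
    grid2 = ordered.reshape(rows, cols, 2)
    if grid2[0, cols - 1, 0] < grid2[0, 0, 0]:
        grid2 = grid2[:, ::-1]
    if grid2[rows - 1, 0, 1] < grid2[0, 0, 1]:
        grid2 = grid2[::-1, :]
    return grid2.reshape(-1, 2)


def collect_pattern_views(
    image_stream,
    pattern: CalibrationPattern,
    n_images: int = DEFAULT_N_VIEWS,
    rate_fps: float = DEFAULT_COLLECTION_FPS,
) -> list[np.ndarray]:
    """Collect exactly ``n_images`` accepted pattern views from a stream.

    Images whose corner detection fails are discarded and do not count.
    ``rate_fps`` documents the nominal collection rate of an online session;
    file streams deliver frames at their own pace.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    views: list[np.ndarray] = []
    for image in image_stream:
        corners = find_chessboard_corners(image, pattern)
        if corners is not None:
            views.append(corners)
            if len(views) == n_images:
                return views
    raise InsufficientViewsError(
        f"stream exhausted after {len(views)} accepted views; {n_images} required"
    )


# ---------------------------------------------------------------------------
# intrinsic calibration (Zhang)
# ---------------------------------------------------------------------------

def _check_views(views, pattern):
    views = [np.asarray(v, dtype=float) for v in views]
    for v in views:
        if v.shape != (pattern.n_corners, 2):
            raise ValueError(
                f"each view must hold {pattern.n_corners} (x, y) corners"
            )
    return views

def _init_intrinsics(views, pattern, image_size):
    """Closed-form focal estimate with the principal point at image centre."""
    cx, cy = (image_size[0] - 1) / 2.0, (image_size[1] - 1) / 2.0
    P_inv = np.array([[1.0, 0.0, -cx], [0.0, 1.0, -cy], [0.0, 0.0, 1.0]])
    rows, rhs = [], []
    Hs = []
    for v in views:
        H = geo.homography_dlt(pattern.grid, v)
        Hs.append(H)
        Hp = P_inv @ H
        h1, h2 = Hp[:, 0], Hp[:, 1]
        rows.append([h1[0] * h2[0], h1[1] * h2[1]])
        rhs.append(-h1[2] * h2[2])
        rows.append([h1[0] ** 2 - h2[0] ** 2, h1[1] ** 2 - h2[1] ** 2])
        rhs.append(-(h1[2] ** 2 - h2[2] ** 2))
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    u, w = sol
    if u <= 0 or w <= 0:  # degenerate closed form; fall back to a long-lens guess
        f = 5.0 * max(image_size)
        return f, f, cx, cy, Hs
    return 1.0 / np.sqrt(u), 1.0 / np.sqrt(w), cx, cy, Hs


def _pack_poses(Rts):
    out = []
    for R, T in Rts:
        out.extend(geo.matrix_to_rotvec(R))
        out.extend(np.asarray(T).ravel())
    return np.asarray(out)


def _bundle_sparsity(n_intr: int, n_views: int, n_pts: int) -> lil_matrix:
    m = 2 * n_pts * n_views
    S = lil_matrix((m, n_intr + 6 * n_views), dtype=int)
    S[:, :n_intr] = 1
    for i in range(n_views):
        S[2 * n_pts * i : 2 * n_pts * (i + 1), n_intr + 6 * i : n_intr + 6 * (i + 1)] = 1
    return S


def calibrate_intrinsics(
    views,
    pattern: CalibrationPattern,
    image_size: tuple[int, int],
    estimate_distortion: bool = True,
    return_extrinsics: bool = False,
):
    """Zhang calibration of a single camera from planar pattern views.

    Parameters
    ----------
    views : list of (N, 2) detected corner arrays (full grids).
    image_size : (width, height) px.
    estimate_distortion : also fit (k1, k2, p1, p2, k3); otherwise fix 0.

    Returns the :class:`CameraIntrinsics` with ``rmse_px``/``mae_px`` filled
    (and the per-view :class:`CameraExtrinsics` when requested).
    """
    views = _check_views(views, pattern)
    if len(views) < 3:
        raise ConditioningError("intrinsic calibration needs at least 3 views")
    fx0, fy0, cx0, cy0, Hs = _init_intrinsics(views, pattern, image_size)
    K0 = geo.intrinsic_matrix(fx0, fy0, cx0, cy0)
    poses0 = [geo.pose_from_homography(H, K0) for H in Hs]

    obj = pattern.ideal_corners
    obs = np.vstack(views)
    n_views, n_pts = len(views), pattern.n_corners
    n_dist = 5 if estimate_distortion else 0
    n_intr = 4 + n_dist

    def residuals(p):
        fx, fy, cx, cy = p[:4]
        dist = p[4 : 4 + n_dist] if n_dist else np.zeros(5)
        K = geo.intrinsic_matrix(fx, fy, cx, cy)
        proj = np.empty_like(obs)
        for i in range(n_views):
            base = n_intr + 6 * i
            R = geo.rotvec_to_matrix(p[base : base + 3])
            T = p[base + 3 : base + 6]
            proj[i * n_pts : (i + 1) * n_pts] = geo.project_points(
                obj, R, T, K, dist
            )
        return (proj - obs).ravel()

    x0 = np.concatenate(
        [[fx0, fy0, cx0, cy0], np.zeros(n_dist), _pack_poses(poses0)]
    )
    sol = least_squares(
        residuals,
        x0,
        jac_sparsity=_bundle_sparsity(n_intr, n_views, n_pts),
        x_scale="jac",
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-12,
        max_nfev=400,
    )
    p = sol.x
    dist = np.zeros(5)
    if n_dist:
        dist = p[4:9]
    intr = CameraIntrinsics(
        fx=float(p[0]), fy=float(p[1]), cx=float(p[2]), cy=float(p[3]),
        dist=dist, image_size=tuple(int(s) for s in image_size),
    )
    extr = []
    for i in range(n_views):
        base = n_intr + 6 * i
        extr.append(
            CameraExtrinsics(
                geo.rotvec_to_matrix(p[base : base + 3]), p[base + 3 : base + 6]
            )
        )
    intr.rmse_px, intr.mae_px = reprojection_errors(views, pattern, intr, extr)
    if return_extrinsics:
        return intr, extr
    return intr


def reprojection_errors(
    observed_corners, pattern: CalibrationPattern,
    intrinsics: CameraIntrinsics, per_view_extrinsics,
) -> tuple[float, float]:
    """Per-point Euclidean (RMSE, MAE) of reprojected pattern corners, px."""
    views = _check_views(observed_corners, pattern)
    if len(views) != len(per_view_extrinsics):
        raise ValueError("one extrinsic pose per view is required")
    obj = pattern.ideal_corners
    dists = []
    for v, ext in zip(views, per_view_extrinsics):
        proj = intrinsics.project(obj, ext.R, ext.T)
        dists.append(np.linalg.norm(proj - v, axis=1))
    d = np.concatenate(dists)
    return float(np.sqrt(np.mean(d**2))), float(np.mean(d))


def solve_view_pose(
    corners: np.ndarray, pattern: CalibrationPattern, intrinsics: CameraIntrinsics
) -> CameraExtrinsics:
    """Pose of one pattern view under fixed intrinsics (PnP refinement)."""
    corners = np.asarray(corners, dtype=float)
    ideal = intrinsics.undistort_points(corners)
    H = geo.homography_dlt(pattern.grid, ideal)
    R0, T0 = geo.pose_from_homography(H, intrinsics.K)
    obj = pattern.ideal_corners

    def residuals(p):
        R = geo.rotvec_to_matrix(p[:3])
        return (intrinsics.project(obj, R, p[3:]) - corners).ravel()

    x0 = np.concatenate([geo.matrix_to_rotvec(R0), T0])
    sol = least_squares(residuals, x0, x_scale="jac", ftol=1e-14, xtol=1e-14)
    return CameraExtrinsics(geo.rotvec_to_matrix(sol.x[:3]), sol.x[3:])


def verify_calibration(
    new_views, pattern: CalibrationPattern, fixed_intrinsics: CameraIntrinsics
) -> float:
    """Held-out MAE reprojection error under fixed camera parameters.

    Only the per-view pose is estimated; K and the distortion coefficients
    stay fixed, so the returned MAE is an unbiased estimate of calibration
    quality rather than an in-sample residual.
    """
    views = _check_views(new_views, pattern)
    if not views:
        raise InsufficientViewsError("no views supplied for verification")
    extr = [solve_view_pose(v, pattern, fixed_intrinsics) for v in views]
    _, mae = reprojection_errors(views, pattern, fixed_intrinsics, extr)
    return mae


# ---------------------------------------------------------------------------
# stereo calibration
# ---------------------------------------------------------------------------

def calibrate_stereo(
    views_main,
    views_secondary,
    pattern: CalibrationPattern,
    intrinsics_main: CameraIntrinsics,
    intrinsics_secondary: CameraIntrinsics,
) -> StereoRig:
    """Estimate the relative pose (R, T) of the secondary camera.

    Intrinsics stay fixed.  Initialised from per-view PnP poses (rotation
    averaged through quaternions), then jointly refined with the per-view
    pattern poses against reprojections in both cameras.  Fills
    ``stereo_rmse_px`` with the combined per-point Euclidean RMSE.
    """
    vm = _check_views(views_main, pattern)
    vs = _check_views(views_secondary, pattern)
    if len(vm) != len(vs) or not vm:
        raise ValueError("stereo calibration needs paired, simultaneous views")
    poses_m = [solve_view_pose(v, pattern, intrinsics_main) for v in vm]
    poses_s = [solve_view_pose(v, pattern, intrinsics_secondary) for v in vs]
    R_rels = [ps.R @ pm.R.T for pm, ps in zip(poses_m, poses_s)]
    R0 = Rotation.from_matrix(np.stack(R_rels)).mean().as_matrix()
    T0 = np.mean(
        [ps.T - Rr @ pm.T for pm, ps, Rr in zip(poses_m, poses_s, R_rels)], axis=0
    )

    obj = pattern.ideal_corners
    obs = np.vstack([np.vstack(vm), np.vstack(vs)])
    n_views, n_pts = len(vm), pattern.n_corners

    def residuals(p):
        R_rel = geo.rotvec_to_matrix(p[:3])
        T_rel = p[3:6]
        proj = np.empty_like(obs)
        off = n_views * n_pts
        for i in range(n_views):
            base = 6 + 6 * i
            Rm = geo.rotvec_to_matrix(p[base : base + 3])
            Tm = p[base + 3 : base + 6]
            proj[i * n_pts : (i + 1) * n_pts] = intrinsics_main.project(obj, Rm, Tm)
            proj[off + i * n_pts : off + (i + 1) * n_pts] = (
                intrinsics_secondary.project(obj, R_rel @ Rm, R_rel @ Tm + T_rel)
            )
        return (proj - obs).ravel()

    x0 = np.concatenate(
        [geo.matrix_to_rotvec(R0), T0, _pack_poses([(e.R, e.T) for e in poses_m])]
    )
    m = obs.size
    S = lil_matrix((m, x0.size), dtype=int)
    S[:, :6] = 1
    blk = 2 * n_pts
    for i in range(n_views):
        S[blk * i : blk * (i + 1), 6 + 6 * i : 12 + 6 * i] = 1
        S[m // 2 + blk * i : m // 2 + blk * (i + 1), 6 + 6 * i : 12 + 6 * i] = 1
    sol = least_squares(
        residuals, x0, jac_sparsity=S, x_scale="jac",
        ftol=1e-14, xtol=1e-14, gtol=1e-12, max_nfev=400,
    )
    res = sol.fun.reshape(-1, 2)
    rmse = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return StereoRig(
        main=intrinsics_main,
        secondary=intrinsics_secondary,
        R=geo.rotvec_to_matrix(sol.x[:3]),
        T=sol.x[3:6],
        stereo_rmse_px=rmse,
    )


def pattern_size_error(
    rig: StereoRig, paired_corner_sets, pattern: CalibrationPattern
) -> float:
    """Absolute-unit calibration error from triangulated square sizes (mm).

    Every pair of corner sets is undistorted and triangulated; each
    adjacent-corner distance is compared with the known square size and the
    mean absolute deviation (mm) is returned (also stored on the rig).
    """
    if rig is None or rig.R is None:
        raise CalibrationStateError("stereo rig is not calibrated")
    pairs = pattern.adjacent_pairs()
    devs = []
    for corners_main, corners_sec in paired_corner_sets:
        cm = rig.main.undistort_points(np.asarray(corners_main, dtype=float))
        cs = rig.secondary.undistort_points(np.asarray(corners_sec, dtype=float))
        PH = geo.triangulate_dlt(rig.M1, rig.M2, cm, cs)
        W = np.where(PH[:, 3] != 0.0, PH[:, 3], 1.0)
        P = PH[:, :3] / W[:, None]
        d = np.linalg.norm(P[pairs[:, 0]] - P[pairs[:, 1]], axis=1)
        devs.append(np.abs(d - pattern.square_size))
    err = float(np.mean(np.concatenate(devs)))
    rig.pattern_error_mm = err
    return err


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _intr_to_dict(c: CameraIntrinsics) -> dict:
    k1, k2, p1, p2, k3 = (float(v) for v in c.dist)
    return {
        "fx": float(c.fx), "fy": float(c.fy), "cx": float(c.cx), "cy": float(c.cy),
        "k1": k1, "k2": k2, "k3": k3, "p1": p1, "p2": p2,
        "width": int(c.image_size[0]), "height": int(c.image_size[1]),
        "rmse_px": None if c.rmse_px is None else float(c.rmse_px),
        "mae_px": None if c.mae_px is None else float(c.mae_px),
    }


def _intr_from_dict(d: dict) -> CameraIntrinsics:
    return CameraIntrinsics(
        fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
        dist=[d["k1"], d["k2"], d["p1"], d["p2"], d["k3"]],
        image_size=(d["width"], d["height"]),
        rmse_px=d.get("rmse_px"), mae_px=d.get("mae_px"),
    )


def save_calibration(rig: StereoRig, pattern: CalibrationPattern, path) -> None:
    """Write the full calibration state as a YAML document.

    Floats are emitted at full (repr) precision, so a load/save round trip
    is bit-exact.
    """
    doc = {
        "pattern": {
            "rows": pattern.rows, "cols": pattern.cols,
            "square_size_mm": float(pattern.square_size),
        },
        "main": _intr_to_dict(rig.main),
        "secondary": _intr_to_dict(rig.secondary),
        "stereo": {
            "R": [float(v) for v in rig.R.ravel()],
            "T_mm": [float(v) for v in rig.T],
            "rmse_px": None if rig.stereo_rmse_px is None else float(rig.stereo_rmse_px),
            "pattern_error_mm": (
                None if rig.pattern_error_mm is None else float(rig.pattern_error_mm)
            ),
        },
        "created_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_calibration(path) -> tuple[StereoRig, CalibrationPattern]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pattern = CalibrationPattern(
        cols=doc["pattern"]["cols"], rows=doc["pattern"]["rows"],
        square_size=doc["pattern"]["square_size_mm"],
    )
    rig = StereoRig(
        main=_intr_from_dict(doc["main"]),
        secondary=_intr_from_dict(doc["secondary"]),
        R=np.asarray(doc["stereo"]["R"], dtype=float).reshape(3, 3),
        T=np.asarray(doc["stereo"]["T_mm"], dtype=float),
        stereo_rmse_px=doc["stereo"].get("rmse_px"),
        pattern_error_mm=doc["stereo"].get("pattern_error_mm"),
    )
    return rig, pattern
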