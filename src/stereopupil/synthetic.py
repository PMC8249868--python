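"""Seeded synthetic eye / stereo-rig generators.

Every stage of the pipeline is testable offline against ground truth from
these generators.  The default geometry reproduces the reference rig:
two 2048 x 1536 px cameras (fx = fy = 14493 px, a 50 mm lens on a 3.45 um
sensor), 75 mm baseline, 8 deg vergence of the secondary camera, 700 mm
working distance — giving an object-space scale of ~0.048 mm/px.

The generators are pure functions of (config, seed): the same seed gives
bit-identical output.  Blink artifacts are modelled statistically (outline
confidence drawn below 1 plus a diameter offset), not photometrically;
matching-point artifacts offset the secondary camera's endpoints so that
the triangulated diameter errs by a configured amount while confidences
stay at 1.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import geometry as geo
from .calibration import CalibrationPattern, CameraIntrinsics, StereoRig
from .detect import EyeImage, PupilFit, fit_ellipse
from .measure import absolute_diameter, major_axis_endpoints, triangulate


@dataclass
class RigConfig:
    baseline_mm: float = 75.0
    vergence_deg: float = 8.0
    working_distance_mm: float = 700.0
    image_size: tuple[int, int] = (2048, 1536)
    fx: float = 14493.0
    fy: float = 14493.0
    cx: float | None = None  # None: image centre
    cy: float | None = None
    dist: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class NoiseConfig:
    endpoint_px_sd: float = 0.05
    corner_px_sd: float = 0.1
    pixel_gray_sd: float = 2.0


@dataclass
class ArtifactConfig:
    blink_fraction: float = 0.005
    blink_conf_range: tuple[float, float] = (0.2, 0.8)
    blink_diameter_offset_mm: float = 0.5
    mismatch_fraction: float = 0.02
    mismatch_offset_mm: float = 0.2


@dataclass
class ObjectConfig:
    diameter_mm: float = 5.0
    grays: dict = field(
        default_factory=lambda: {"pupil": 30, "iris": 140, "sclera": 200}
    )


@dataclass
class SimConfig:
    rig: RigConfig = field(default_factory=RigConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    object: ObjectConfig = field(default_factory=ObjectConfig)
    seed: int = 0

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            rig=RigConfig(**{**doc.get("rig", {}),
                             **{k: tuple(v) for k, v in doc.get("rig", {}).items()
                                if k in ("image_size", "dist")}}),
            noise=NoiseConfig(**doc.get("noise", {})),
            artifacts=ArtifactConfig(**{
                **doc.get("artifacts", {}),
                **{k: tuple(v) for k, v in doc.get("artifacts", {}).items()
                   if k == "blink_conf_range"}}),
            object=ObjectConfig(**doc.get("object", {})),
            seed=int(doc.get("seed", 0)),
        )


def build_rig(cfg: RigConfig) -> StereoRig:
    """The true (error-free) stereo rig implied by a rig configuration.

    The secondary camera sits ``baseline_mm`` along +x and is rotated by
    ``vergence_deg`` about the vertical axis toward the main camera's
    optical axis.
    """
    w, h = cfg.image_size
    cx = (w - 1) / 2.0 if cfg.cx is None else cfg.cx
    cy = (h - 1) / 2.0 if cfg.cy is None else cfg.cy
    intr = dict(fx=cfg.fx, fy=cfg.fy, cx=cx, cy=cy,
                dist=np.asarray(cfg.dist, dtype=float),
                image_size=(w, h))
    main = CameraIntrinsics(**intr)
    secondary = CameraIntrinsics(**intr)
    phi = math.radians(cfg.vergence_deg)
    R = np.array(
        [[math.cos(phi), 0.0, math.sin(phi)],
         [0.0, 1.0, 0.0],
         [-math.sin(phi), 0.0, math.cos(phi)]]
    )
    C2 = np.array([cfg.baseline_mm, 0.0, 0.0])
    return StereoRig(main=main, secondary=secondary, R=R, T=-R @ C2)


def mm_per_px(cfg: RigConfig) -> float:
    """Object-space scale at the working distance (thin-pinhole)."""
    return cfg.working_distance_mm / cfg.fx


def _camera_chain(rig: StereoRig):
    return (
        (np.eye(3), np.zeros(3), rig.main),
        (rig.R, rig.T, rig.secondary),
    )


def project_ellipse(
    rig: StereoRig, object_center_mm, diameter_mm: float, n_samples: int = 720
) -> tuple[PupilFit, PupilFit]:
    """Exact image ellipses of a fronto-parallel world circle.

    The circle (diameter in mm, plane normal along the main optical axis)
    is sampled densely, projected through each camera model including
    distortion, and the exact image ellipse recovered by a conic fit (the
    perspective image of a circle is an ellipse, so the fit is exact up to
    numerics).
    """
    c = np.asarray(object_center_mm, dtype=float)
    t = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    r = diameter_mm / 2.0
    circle = c + np.column_stack(
        [r * np.cos(t), r * np.sin(t), np.zeros_like(t)]
    )
    fits = []
    for R, T, intr in _camera_chain(rig):
        if (R @ c + T)[2] <= 0:
            raise ValueError("object must lie in front of both cameras")
        px = geo.project_points(circle, R, T, intr.K, intr.dist)
        (cx, cy), a, b, theta = fit_ellipse(px)
        fits.append(
            PupilFit(center=(cx, cy), major_axis=2 * a, minor_axis=2 * b,
                     angle=theta, outline_confidence=1.0, valid=True)
        )
    return fits[0], fits[1]


# ---------------------------------------------------------------------------
# eye-image rendering
# ---------------------------------------------------------------------------

def _coverage(dist_px: np.ndarray) -> np.ndarray:
    """Anti-aliased coverage from an approximate signed distance (px)."""
    return np.clip(0.5 - dist_px, 0.0, 1.0)


def _ellipse_distance(xx, yy, center, A, B, theta_deg):
    th = math.radians(theta_deg)
    dx, dy = xx - center[0], yy - center[1]
    xr = dx * math.cos(th) + dy * math.sin(th)
    yr = -dx * math.sin(th) + dy * math.cos(th)
    rho = np.sqrt((xr / A) ** 2 + (yr / B) ** 2)
    grad = np.sqrt((xr / A**2) ** 2 + (yr / B**2) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(grad > 0, (rho - 1.0) * rho / np.maximum(grad, 1e-12), -A)
    return d


def render_eye_image(
    ellipse: PupilFit,
    grays: dict | None = None,
    pixel_gray_sd: float = 0.0,
    seed: int = 0,
    image_size: tuple[int, int] = (512, 512),
    frame_count: int = 0,
    iris_scale: float = 2.2,
) -> EyeImage:
    """Render a dark-pupil NIR-style eye image with known ground truth.

    An anti-aliased dark pupil ellipse sits on a brighter iris disk on a
    sclera background; additive Gaussian pixel noise is clipped to
    [0, 255].  The pupil ellipse must lie inside the frame.
    """
    grays = grays or {"pupil": 30, "iris": 140, "sclera": 200}
    w, h = image_size
    A, B = ellipse.major_axis / 2.0, ellipse.minor_axis / 2.0
    th = math.radians(ellipse.angle)
    ex = math.hypot(A * math.cos(th), B * math.sin(th))
    ey = math.hypot(A * math.sin(th), B * math.cos(th))
    cx, cy = ellipse.center
    if cx - ex < 0 or cx + ex > w - 1 or cy - ey < 0 or cy + ey > h - 1:
        raise ValueError("pupil ellipse must lie inside the frame")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), float(grays["sclera"]))
    iris_r = iris_scale * A
    d_iris = np.hypot(xx - cx, yy - cy) - iris_r
    img += (_coverage(d_iris)) * (grays["iris"] - img)
    d_pupil = _ellipse_distance(xx, yy, (cx, cy), A, B, ellipse.angle)
    img += (_coverage(d_pupil)) * (grays["pupil"] - img)
    if pixel_gray_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, pixel_gray_sd, img.shape)
    return EyeImage(np.clip(np.round(img), 0, 255).astype(np.uint8),
                    frame_count=frame_count)


def render_chessboard_view(
    pattern: CalibrationPattern,
    R: np.ndarray,
    T: np.ndarray,
    intrinsics: CameraIntrinsics,
    supersample: int = 2,
    grays: tuple[int, int, int] = (30, 220, 128),
) -> np.ndarray:
    """Render a posed chessboard (dark/light squares on a mid-gray ground).

    Inverse-maps pixel coordinates to the pattern plane through the plane
    homography (distortion-free rendering) with ``supersample`` x
    ``supersample`` antialiasing.  Returns a uint8 image.
    """
    w, h = intrinsics.image_size
    K = intrinsics.K
    H = K @ np.column_stack([R[:, 0], R[:, 1], np.asarray(T).ravel()])
    Hinv = np.linalg.inv(H)
    s = pattern.square_size
    ss = supersample
    step = 1.0 / ss
    offs = (np.arange(ss) - (ss - 1) / 2.0) * step
    acc = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    black, white, bg = grays
    for oy in offs:
        for ox in offs:
            pts = np.stack([xx + ox, yy + oy, np.ones_like(xx)], axis=-1)
            q = pts @ Hinv.T
            u = q[..., 0] / q[..., 2]
            v = q[..., 1] / q[..., 2]
            on_board = (
                (u >= -s) & (u <= pattern.cols * s)
                & (v >= -s) & (v <= pattern.rows * s)
            )
            parity = (np.floor(u / s) + np.floor(v / s)) % 2
            shade = np.where(parity == 0, white, black)
            acc += np.where(on_board, shade, bg)
    return np.clip(np.round(acc / ss**2), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# calibration-pattern views
# ---------------------------------------------------------------------------

@dataclass
class PatternViews:
    """Noisy + true projected corner sets with their generating poses."""

    main: list  # noisy (N, 2) corner arrays
    secondary: list | None
    true_main: list
    true_secondary: list | None
    poses: list  # (R, T) of the pattern in the main-camera frame


def _sample_pose(rng, pattern: CalibrationPattern, cfg: RigConfig):
    """One candidate pattern pose: free roll, tilt up to 30 deg, near the
    working distance.  In-view feasibility is left to rejection sampling
    (a verged stereo rig shares only a narrow field, so many candidates are
    rejected when both cameras must see every corner)."""
    tilt = math.radians(rng.uniform(0.0, 30.0))
    axis_ang = rng.uniform(0.0, 2.0 * math.pi)
    axis = np.array([math.cos(axis_ang), math.sin(axis_ang), 0.0])
    roll = math.radians(rng.uniform(0.0, 360.0))
    Rz = np.array(
        [[math.cos(roll), -math.sin(roll), 0.0],
         [math.sin(roll), math.cos(roll), 0.0],
         [0.0, 0.0, 1.0]]
    )
    ca, sa = math.cos(tilt), math.sin(tilt)
    K = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]],
         [-axis[1], axis[0], 0.0]]
    )
    Rtilt = np.eye(3) + sa * K + (1.0 - ca) * (K @ K)
    R = Rtilt @ Rz
    target = np.array(
        [rng.uniform(-40.0, 25.0), rng.uniform(-12.0, 12.0),
         cfg.working_distance_mm * rng.uniform(1.0, 1.3)]
    )
    center = np.array(
        [(pattern.cols - 1) * pattern.square_size / 2.0,
         (pattern.rows - 1) * pattern.square_size / 2.0, 0.0]
    )
    T = target - R @ center
    return R, T


def generate_pattern_views(
    cfg: SimConfig,
    pattern: CalibrationPattern | None = None,
    n_views: int = 30,
    corner_px_sd: float | None = None,
    seed: int | None = None,
    stereo: bool = True,
    margin_px: float = 30.0,
) -> PatternViews:
    """Random in-view pattern poses with exact + noisy projected corners.

    Poses span tilts up to 30 deg about random in-plane axes; poses whose
    corners leave either requested camera's frame (margin ``margin_px``)
    are rejected and resampled.
    """
    if n_views < 3:
        raise ValueError("n_views must be >= 3")
    pattern = pattern or CalibrationPattern()
    sd = cfg.noise.corner_px_sd if corner_px_sd is None else corner_px_sd
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rig = build_rig(cfg.rig)
    w, h = cfg.rig.image_size
    obj = pattern.ideal_corners
    cams = _camera_chain(rig) if stereo else _camera_chain(rig)[:1]

    out = PatternViews([], [] if stereo else None, [],
                       [] if stereo else None, [])
    attempts = 0
    while len(out.main) < n_views:
        attempts += 1
        if attempts > 1000 * n_views:
            raise RuntimeError("pose rejection sampling failed to converge")
        R, T = _sample_pose(rng, pattern, cfg.rig)
        projections = []
        ok = True
        for Rc, Tc, intr in cams:
            Xc = obj @ (Rc @ R).T + (Rc @ T + Tc)
            if np.any(Xc[:, 2] <= 0):
                ok = False
                break
            px = geo.project_points(obj, Rc @ R, Rc @ T + Tc, intr.K, intr.dist)
            if (px[:, 0].min() < margin_px or px[:, 0].max() > w - 1 - margin_px
                    or px[:, 1].min() < margin_px
                    or px[:, 1].max() > h - 1 - margin_px):
                ok = False
                break
            projections.append(px)
        if not ok:
            continue
        out.poses.append((R, T))
        out.true_main.append(projections[0])
        out.main.append(projections[0] + rng.normal(0.0, sd, projections[0].shape))
        if stereo:
            out.true_secondary.append(projections[1])
            out.secondary.append(
                projections[1] + rng.normal(0.0, sd, projections[1].shape)
            )
    return out


def pattern_image_stream(
    cfg: SimConfig,
    pattern: CalibrationPattern,
    n_views: int,
    seed: int | None = None,
    blank_every: int | None = None,
):
    """Yield rendered chessboard EyeImages (optionally interleaving blanks).

    Emulates an online calibration session feeding
    :func:`stereopupil.calibration.collect_pattern_views`; every
    ``blank_every``-th frame is a patternless gray image that detection must
    discard.
    """
    views = generate_pattern_views(
        cfg, pattern, n_views=n_views, corner_px_sd=0.0, seed=seed, stereo=False
    )
    rig = build_rig(cfg.rig)
    fc = 0
    for i, (R, T) in enumerate(views.poses):
        if blank_every and i and i % blank_every == 0:
            w, h = cfg.rig.image_size
            yield EyeImage(np.full((h, w), 128, dtype=np.uint8), frame_count=fc)
            fc += 1
        yield EyeImage(
            render_chessboard_view(pattern, R, T, rig.main), frame_count=fc
        )
        fc += 1


# ---------------------------------------------------------------------------
# reference-object measurement sequences
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSequence:
    """Paired pupil fits with per-frame artifact labels and ground truth."""

    fits_main: list
    fits_secondary: list
    labels: np.ndarray  # {"clean", "blink", "mismatch"} per frame
    true_diameter_mm: np.ndarray
    frame_counts: np.ndarray
    rig: StereoRig

    def __len__(self):
        return len(self.fits_main)

    def measured_diameters(self) -> np.ndarray:
        """Triangulated diameter per frame (NaN where a fit is invalid)."""
        out = np.full(len(self), np.nan)
        for i, (fm, fs) in enumerate(zip(self.fits_main, self.fits_secondary)):
            d = absolute_diameter(fm, fs, self.rig)
            if d is not None:
                out[i] = d
        return out


def _shifted_endpoints(e: np.ndarray, shift_px: float) -> np.ndarray:
    """Move both endpoints outward along the axis by ``shift_px`` each."""
    u = (e[1] - e[0]) / np.linalg.norm(e[1] - e[0])
    return np.vstack([e[0] - shift_px * u, e[1] + shift_px * u])


def _probe_slopes(rig, e_main, e_sec):
    """mm of diameter change per px of outward endpoint shift."""
    def diam(em, es):
        P = triangulate(em, es, rig)
        return float(np.linalg.norm(P[0] - P[1]))

    d0 = diam(e_main, e_sec)
    both = diam(_shifted_endpoints(e_main, 1.0), _shifted_endpoints(e_sec, 1.0))
    sec = diam(e_main, _shifted_endpoints(e_sec, 1.0))
    return both - d0, sec - d0


def simulate_reference_sequence(cfg: SimConfig, n_frames: int) -> SimulatedSequence:
    """Stereo pupil-fit series of a fixed reference object with artifacts.

    Per frame, the true image endpoints of the object's major axis are
    perturbed by Gaussian noise (``endpoint_px_sd``).  Blink frames get an
    outline confidence drawn uniformly from ``blink_conf_range`` and a
    diameter offset of ``blink_diameter_offset_mm``; mismatch frames keep
    confidence 1 but shift the secondary camera's endpoints so the
    triangulated diameter errs by ``mismatch_offset_mm`` (random sign),
    which also perturbs that camera's axis ratio.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rig = build_rig(cfg.rig)
    center = np.array([0.0, 0.0, cfg.rig.working_distance_mm])
    fit_m, fit_s = project_ellipse(rig, center, cfg.object.diameter_mm)
    e_main = major_axis_endpoints(fit_m)
    e_sec = major_axis_endpoints(fit_s)
    slope_both, slope_sec = _probe_slopes(rig, e_main, e_sec)
    shift_blink = cfg.artifacts.blink_diameter_offset_mm / slope_both
    shift_mismatch = cfg.artifacts.mismatch_offset_mm / slope_sec

    rng = np.random.default_rng(cfg.seed)
    u = rng.random(n_frames)
    bf, mf = cfg.artifacts.blink_fraction, cfg.artifacts.mismatch_fraction
    labels = np.where(u < bf, "blink", np.where(u < bf + mf, "mismatch", "clean"))
    signs = rng.choice([-1.0, 1.0], size=n_frames)
    sd = cfg.noise.endpoint_px_sd
    blink_lo, blink_hi = cfg.artifacts.blink_conf_range

    fits_main, fits_sec = [], []
    for i in range(n_frames):
        em = e_main + rng.normal(0.0, sd, (2, 2))
        es = e_sec + rng.normal(0.0, sd, (2, 2))
        conf_m = conf_s = 1.0
        if labels[i] == "blink":
            em = _shifted_endpoints(em, signs[i] * shift_blink)
            es = _shifted_endpoints(es, signs[i] * shift_blink)
            conf_m = rng.uniform(blink_lo, blink_hi)
            conf_s = rng.uniform(blink_lo, blink_hi)
        elif labels[i] == "mismatch":
            es = _shifted_endpoints(es, signs[i] * shift_mismatch)
        fits_main.append(_fit_from_endpoints(em, fit_m.minor_axis, sd, rng, conf_m))
        fits_sec.append(_fit_from_endpoints(es, fit_s.minor_axis, sd, rng, conf_s))
    return SimulatedSequence(
        fits_main=fits_main,
        fits_secondary=fits_sec,
        labels=labels,
        true_diameter_mm=np.full(n_frames, cfg.object.diameter_mm),
        frame_counts=np.arange(n_frames),
        rig=rig,
    )


def _fit_from_endpoints(e, true_minor, sd, rng, conf):
    d = e[1] - e[0]
    a = float(np.linalg.norm(d))
    b = float(true_minor + rng.normal(0.0, math.sqrt(2.0) * sd))
    b = min(b, a)  # a fitted minor axis never exceeds the major axis
    theta = math.degrees(math.atan2(d[1], d[0])) % 180.0
    c = e.mean(axis=0)
    return PupilFit(center=(float(c[0]), float(c[1])), major_axis=a, minor_axis=b,
                    angle=theta, outline_confidence=float(conf), valid=True)


# ---------------------------------------------------------------------------
# pupil trajectory protocol
# ---------------------------------------------------------------------------

def pupil_trajectory(
    protocol,
    baseline_mm: float = 6.0,
    amplitude_mm: float = 3.0,
    tau_s: float = 1.5,
):
    """Piecewise-exponential diameter trajectory for a stimulus protocol.

    ``protocol`` lists ``(onset_s, duration_s, target_mm)`` stimuli; the
    diameter approaches each (clamped) target with time constant ``tau_s``
    and relaxes back to baseline between stimuli.  Returns a vectorised
    callable ``d(t)`` bounded to [1, 9] mm.
    """
    events = sorted((float(o), float(du), float(tg)) for o, du, tg in protocol)
    for (o1, d1, _), (o2, _, _) in zip(events, events[1:]):
        if o1 + d1 > o2:
            raise ValueError("stimuli must not overlap")
    lo = max(1.0, baseline_mm - amplitude_mm)
    hi = min(9.0, baseline_mm + amplitude_mm)

    # segment list: (t_start, start_value, target)
    segments = [(-math.inf, baseline_mm, baseline_mm)]
    value, t_prev, target_prev = baseline_mm, 0.0, baseline_mm
    for onset, dur, tgt in events:
        value = target_prev + (value - target_prev) * math.exp(
            -(onset - t_prev) / tau_s
        )
        tgt = min(max(tgt, lo), hi)
        segments.append((onset, value, tgt))
        value = tgt + (value - tgt) * math.exp(-dur / tau_s)
        segments.append((onset + dur, value, baseline_mm))
        t_prev, target_prev = onset + dur, baseline_mm

    starts = np.array([s[0] for s in segments])

    def diameter(t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(segments) - 1)
        out = np.empty_like(t, dtype=float)
        for k in np.unique(idx):
            t0, v0, tg = segments[k]
            tt = t[idx == k]
            if math.isinf(t0):
                out[idx == k] = v0
            else:
                out[idx == k] = tg + (v0 - tg) * np.exp(-(tt - t0) / tau_s)
        return np.clip(out, 1.0, 9.0)

    return diameter


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_image_sequence(
    directory, images, fmt: str = "bmp", prefix: str = "img"
) -> list[Path]:
    """Write EyeImages as ``<prefix>_<frame_count:06d>.<fmt>`` files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for img in images:
        p = directory / f"{prefix}_{img.frame_count:06d}.{fmt}"
        iio.imwrite(p, img.pixels)
        paths.append(p)
    return paths


def write_truth_csv(seq: SimulatedSequence, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "frame_count": seq.frame_counts,
            "label": seq.labels,
            "true_diameter_mm": seq.true_diameter_mm,
        }
    ).to_csv(path, index=False)
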