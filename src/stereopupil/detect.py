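"""Dark-pupil detection and fit-quality metrics.

The baseline detector targets NIR dark-pupil images, where the pupil images
as a dark elliptical spot on the brighter iris.  It follows the canonical
pipeline for this image class: intensity thresholding, morphological
clean-up, connected-component selection, sub-pixel boundary extraction and a
least-squares ellipse fit.  Third-party detectors plug in through
:class:`PupilDetector`.

Conventions
-----------
* Image frame: origin at the centre of the top-left pixel, x rightward,
  y downward, 0-based; all pixel quantities are sub-pixel capable.
* Ellipse angle ``theta``: degrees, counterclockwise from +x to the major
  axis, normalised to ``[0, 180)``.
* :func:`fit_ellipse` reports *semi*-axes (the conic parameters);
  :class:`PupilFit` stores *full* axis lengths, so that
  ``diameter_px == major_axis``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .errors import DegenerateInputError, InvalidFitError

#: Saturation contrast (gray levels) at which outline confidence reaches 1.
DEFAULT_T_SAT = 25.0

#: Sector count for the angular edge-spread metric (octants).
DEFAULT_N_BINS = 8


@dataclass
class EyeImage:
    """One grayscale eye image plus acquisition metadata."""

    pixels: np.ndarray
    frame_count: int = 0
    timestamp: float | None = None  # ms since Unix epoch; None in offline mode
    camera_id: str = "mono"  # {"main", "secondary", "mono"}
    source_name: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("EyeImage requires a non-empty 2-D pixel grid")
        if px.dtype != np.uint8:
            px = np.clip(np.round(px), 0, 255).astype(np.uint8)
        self.pixels = px
        if self.frame_count < 0:
            raise ValueError("frame_count must be nonnegative")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PupilFit:
    """A detected pupil: fitted ellipse, confidences and validity.

    ``major_axis``/``minor_axis`` are full lengths (px); the reported pupil
    diameter equals the major axis.
    """

    center: tuple[float, float] = (math.nan, math.nan)
    major_axis: float = math.nan
    minor_axis: float = math.nan
    angle: float = math.nan  # degrees in [0, 180)
    algorithm_confidence: float | None = None
    outline_confidence: float = 0.0
    valid: bool = False

    @property
    def diameter_px(self) -> float:
        return self.major_axis

    @property
    def circumference_px(self) -> float:
        """Ellipse perimeter by Ramanujan's first approximation."""
        if not self.valid:
            return math.nan
        A, B = self.major_axis / 2.0, self.minor_axis / 2.0
        return math.pi * (3.0 * (A + B) - math.sqrt((3.0 * A + B) * (A + 3.0 * B)))

    @property
    def axis_ratio(self) -> float:
        return axis_ratio(self)

    @classmethod
    def invalid(cls) -> "PupilFit":
        return cls()


@dataclass
class DetectorParams:
    """Tunables of the baseline threshold detector.

    roi : optional (x, y, w, h) rectangle, full-image coordinates.
    threshold_percentile : fraction of darkest pixels assumed to be pupil.
    min_area, max_area : component area gates in px^2 (max_area None means
        40% of the searched region).
    min_axis_ratio : reject fits more eccentric than this minor/major ratio.
    morphology_radius : structuring-element radius for open+close, px.
    """

    roi: tuple[int, int, int, int] | None = None
    threshold_percentile: float = 0.001
    min_area: float = 150.0
    max_area: float | None = None
    min_axis_ratio: float = 0.2
    morphology_radius: int = 2
    t_sat: float = DEFAULT_T_SAT
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self):
        if not 0.0 < self.min_axis_ratio <= 1.0:
            raise ValueError("min_axis_ratio must be in (0, 1]")
        if self.max_area is not None and self.min_area >= self.max_area:
            raise ValueError("min_area must be smaller than max_area")


def fit_ellipse(points) -> tuple[tuple[float, float], float, float, float]:
    """Least-squares conic (ellipse) fit to >= 5 boundary points.

    Returns ``((cx, cy), a, b, theta_deg)`` with *semi*-axes ``a >= b`` and
    ``theta`` in ``[0, 180)``.  Raises :class:`DegenerateInputError` for
    fewer than 5 points or a degenerate (e.g. collinear) configuration.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 5 or pts.shape[1] != 2:
        raise DegenerateInputError("ellipse fit needs at least 5 (x, y) points")
    with np.errstate(divide="ignore", invalid="ignore"):
        model = skmeasure.EllipseModel.from_estimate(pts)
    if not model:
        raise DegenerateInputError("degenerate point configuration for ellipse fit")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise DegenerateInputError("ellipse fit did not converge to a real ellipse")
    theta = math.degrees(theta)
    if b > a:
        a, b = b, a
        theta += 90.0
    theta %= 180.0
    return (float(xc), float(yc)), float(a), float(b), float(theta)


def axis_ratio(fit: PupilFit) -> float:
    """Minor/major axis ratio in (0, 1] of a valid fit."""
    if not fit.valid:
        raise InvalidFitError("axis ratio is undefined for an invalid fit")
    return fit.minor_axis / fit.major_axis


def _boundary_normals(fit: PupilFit, n: int = 360) -> tuple[np.ndarray, np.ndarray]:
    """Points on the fitted ellipse and their outward unit normals."""
    A, B = fit.major_axis / 2.0, fit.minor_axis / 2.0
    th = math.radians(fit.angle)
    u = np.array([math.cos(th), math.sin(th)])
    v = np.array([-math.sin(th), math.cos(th)])
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    pts = (
        np.asarray(fit.center)
        + np.outer(A * np.cos(t), u)
        + np.outer(B * np.sin(t), v)
    )
    normals = np.outer(B * np.cos(t), u) + np.outer(A * np.sin(t), v)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return pts, normals


def _band_mean(image: np.ndarray, pts: np.ndarray, normals: np.ndarray,
               offsets: np.ndarray) -> float:
    samples = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    cols = samples[..., 0].ravel()
    rows = samples[..., 1].ravel()
    vals = ndimage.map_coordinates(
        image.astype(float), np.vstack([rows, cols]), order=1, mode="nearest"
    )
    return float(vals.mean())


def outline_confidence(
    image: EyeImage | np.ndarray,
    fit: PupilFit,
    band_px: float = 3.0,
    t_sat: float = DEFAULT_T_SAT,
) -> float:
    """Contrast-based confidence of a pupil fit in ``[0, 1]``.

    Mean intensity is sampled over a band of width ``band_px`` just inside
    (``mu_in``) and just outside (``mu_out``) the fitted ellipse boundary;
    the score is ``clip((mu_out - mu_in) / t_sat, 0, 1)``, saturating at the
    full dark-pupil contrast ``t_sat`` (gray levels).
    """
    if not fit.valid:
        warnings.warn("outline confidence of an invalid fit is 0", stacklevel=2)
        return 0.0
    if band_px < 1:
        raise ValueError("band_px must be >= 1")
    px = image.pixels if isinstance(image, EyeImage) else np.asarray(image)
    pts, normals = _boundary_normals(fit)
    # offsets start 1 px off the boundary so anti-aliased edge pixels do not
    # dilute either band
    offsets = np.linspace(1.0, float(band_px), num=max(2, int(round(band_px))))
    mu_in = _band_mean(px, pts, normals, -offsets)
    mu_out = _band_mean(px, pts, normals, offsets)
    return float(np.clip((mu_out - mu_in) / t_sat, 0.0, 1.0))


def angular_edge_spread(
    support_points, fit: PupilFit, n_bins: int = DEFAULT_N_BINS
) -> float:
    """Fraction of angular sectors about the centre holding support points."""
    if not fit.valid:
        raise InvalidFitError("edge spread is undefined for an invalid fit")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pts = np.atleast_2d(np.asarray(support_points, dtype=float))
    if pts.size == 0:
        return 0.0
    ang = np.arctan2(pts[:, 1] - fit.center[1], pts[:, 0] - fit.center[0])
    bins = np.floor((ang + math.pi) / (2.0 * math.pi) * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    return float(np.unique(bins).size) / float(n_bins)


def general_confidence(outline: float, ratio: float, spread: float) -> float:
    """Arithmetic mean of the three fit-quality metrics."""
    for v in (outline, ratio, spread):
        if not 0.0 <= v <= 1.0:
            raise ValueError("confidence inputs must be in [0, 1]")
    return (outline + ratio + spread) / 3.0


def _candidate_components(mask: np.ndarray, params: DetectorParams,
                          region_area: float):
    max_area = params.max_area if params.max_area is not None else 0.4 * region_area
    labels = skmeasure.label(mask)
    out = []
    for region in skmeasure.regionprops(labels):
        if not params.min_area <= region.area <= max_area:
            continue
        if region.axis_major_length <= 0:
            continue
        r = region.axis_minor_length / region.axis_major_length
        if r < params.min_axis_ratio:
            continue
        out.append(region)
    return out


def _subpixel_boundary(image: np.ndarray, region, level: float) -> np.ndarray | None:
    """Iso-contour of the pupil edge around one component, full-image coords."""
    minr, minc, maxr, maxc = region.bbox
    margin = 5
    r0, c0 = max(minr - margin, 0), max(minc - margin, 0)
    crop = image[r0 : min(maxr + margin, image.shape[0]),
                 c0 : min(maxc + margin, image.shape[1])].astype(float)
    contours = skmeasure.find_contours(crop, level)
    if not contours:
        return None
    cy, cx = region.centroid
    best, best_d = None, np.inf
    for cont in contours:
        if cont.shape[0] < 5:
            continue
        d = np.hypot(cont[:, 0].mean() + r0 - cy, cont[:, 1].mean() + c0 - cx)
        if d < best_d:
            best, best_d = cont, d
    if best is None:
        return None
    return np.column_stack([best[:, 1] + c0, best[:, 0] + r0])  # (x, y)


def detect_pupil(image: EyeImage, params: DetectorParams | None = None) -> PupilFit:
    """Detect the dark pupil in a grayscale eye image.

    Returns a valid :class:`PupilFit` (full-image coordinates, even when an
    ROI was used) when a candidate passes the area and axis-ratio gates;
    otherwise an invalid fit.  Never raises on a well-formed image.
    """
    if params is None:
        params = DetectorParams()
    if not isinstance(image, EyeImage):
        image = EyeImage(np.asarray(image))
    px = image.pixels
    if params.roi is not None:
        x, y, w, h = (int(v) for v in params.roi)
        if x < 0 or y < 0 or w < 1 or h < 1 or x + w > image.width or y + h > image.height:
            raise ValueError("roi must lie inside the image")
        sub = px[y : y + h, x : x + w]
        offset = (x, y)
    else:
        sub = px
        offset = (0, 0)

    # dark anchor inside the pupil (darkest percentile) against the region
    # median; the midpoint separates pupil from iris regardless of pupil size
    dark = float(np.percentile(sub, params.threshold_percentile * 100.0))
    thr = 0.5 * (dark + float(np.median(sub)))
    mask = sub <= thr
    if params.morphology_radius > 0:
        footprint = skmorph.disk(params.morphology_radius)
        mask = skmorph.closing(skmorph.opening(mask, footprint), footprint)

    candidates = _candidate_components(mask, params, float(sub.size))
    if not candidates:
        return PupilFit.invalid()
    best_area = max(r.area for r in candidates)
    finalists = [r for r in candidates if r.area == best_area]
    # dark-pupil tie-break: among equal-area components the darkest interior wins
    region = min(finalists, key=lambda r: sub[tuple(np.asarray(r.coords).T)].mean())

    interior = float(sub[tuple(np.asarray(region.coords).T)].mean())
    ring = skmorph.dilation(
        skmeasure.label(mask) == region.label, skmorph.disk(4)
    ) & ~mask
    surround = float(sub[ring].mean()) if ring.any() else interior + 2.0 * params.t_sat
    level = 0.5 * (interior + surround)

    boundary = _subpixel_boundary(sub, region, level)
    if boundary is None or boundary.shape[0] < 5:
        return PupilFit.invalid()
    try:
        (cx, cy), a_semi, b_semi, theta = fit_ellipse(boundary)
    except DegenerateInputError:
        return PupilFit.invalid()
    if b_semi / a_semi < params.min_axis_ratio:
        return PupilFit.invalid()

    fit = PupilFit(
        center=(cx + offset[0], cy + offset[1]),
        major_axis=2.0 * a_semi,
        minor_axis=2.0 * b_semi,
        angle=theta,
        valid=True,
    )
    band = max(2.0, 0.05 * fit.major_axis)
    fit.outline_confidence = outline_confidence(px, fit, band_px=band, t_sat=params.t_sat)
    support = boundary + np.asarray(offset, dtype=float)
    spread = angular_edge_spread(support, fit, n_bins=params.n_bins)
    fit.algorithm_confidence = None
    # keep the spread score around for detector-level consumers
    fit._spread = spread  # type: ignore[attr-defined]
    return fit


class PupilDetector:
    """Pluggable detection interface: ``run(image) -> PupilFit``.

    Implementations with a native confidence return True from
    :meth:`has_confidence` and populate ``algorithm_confidence``; otherwise
    the pipeline falls back to :func:`general_confidence`.
    """

    name = "abstract"

    def run(self, image: EyeImage) -> PupilFit:  # pragma: no cover - interface
        raise NotImplementedError

    def has_confidence(self) -> bool:
        return False


class ThresholdPupilDetector(PupilDetector):
    """Baseline dark-pupil detector (threshold + morphology + ellipse fit)."""

    name = "threshold"

    def __init__(self, params: DetectorParams | None = None):
        self.params = params or DetectorParams()

    def run(self, image: EyeImage) -> PupilFit:
        return detect_pupil(image, self.params)
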