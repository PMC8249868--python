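"""Trigger protocol, recording-rate arithmetic, CSV records, file camera.

The hardware trigger is a symmetric (50% duty) square wave whose rising
edges each trigger one frame, commanded over UART with the string
``<Tx{COUNT_OF_TRIGGER}x{TIME_TRIGGER_ON}>`` — 'x' separates the two
fields and ``TIME_TRIGGER_ON`` is the pulse width in microseconds, so a
10 ms frame interval corresponds to a 5000 us pulse.

Measurement CSVs use one fixed header; columns are keyed by name on read,
floats are written at 6 decimals and missing values as empty fields.
Recording-rate figures use decimal megabytes (1 MB = 10^6 bytes).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detect import EyeImage, PupilFit
from .errors import RowError, SchemaError

_TRIGGER_RE = re.compile(r"^<Tx(\d+)x(\d+)>$")

CSV_HEADER = [
    "filename", "timestamp_ms",
    "main_width_px", "main_height_px", "main_center_x_px", "main_center_y_px",
    "main_angle_deg", "main_diameter_px", "main_circumference_px",
    "main_confidence", "main_outline_confidence",
    "sec_width_px", "sec_height_px", "sec_center_x_px", "sec_center_y_px",
    "sec_angle_deg", "sec_diameter_px", "sec_circumference_px",
    "sec_confidence", "sec_outline_confidence",
    "physical_diameter_mm",
]

_STR_FIELDS = {"filename"}


@dataclass
class TriggerCommand:
    count_of_trigger: int
    time_trigger_on_us: int

    def __post_init__(self):
        if self.count_of_trigger <= 0 or self.time_trigger_on_us <= 0:
            raise ValueError("trigger parameters must be positive integers")


def format_trigger(cmd: TriggerCommand) -> str:
    return f"<Tx{cmd.count_of_trigger}x{cmd.time_trigger_on_us}>"


def parse_trigger(text: str) -> TriggerCommand:
    m = _TRIGGER_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed trigger command: {text!r}")
    return TriggerCommand(int(m.group(1)), int(m.group(2)))


def pulse_for_rate(frame_interval_ms: float) -> float:
    """Pulse width (us) of a 50%-duty square wave for a frame interval."""
    if frame_interval_ms <= 0:
        raise ValueError("frame interval must be positive")
    return frame_interval_ms * 1000.0 / 2.0


def rate_for_pulse(pulse_us: float) -> float:
    """Frame rate (fps) implied by a pulse width under 50% duty."""
    if pulse_us <= 0:
        raise ValueError("pulse width must be positive")
    return 1e6 / (2.0 * pulse_us)


def frame_megabytes(width: int, height: int, bit_depth: int = 8) -> float:
    """Uncompressed frame size in decimal MB (10^6 bytes)."""
    if width <= 0 or height <= 0:
        raise ValueError("dimensions must be positive")
    if bit_depth % 8:
        raise ValueError("bit depth must be a multiple of 8")
    return width * height * (bit_depth // 8) / 1e6


def required_write_rate(frame_mb: float, fps: float, n_cameras: int = 1) -> float:
    """Sustained disk bandwidth (MB/s) needed to record raw frames."""
    if frame_mb <= 0 or fps <= 0 or n_cameras <= 0:
        raise ValueError("inputs must be positive")
    return frame_mb * fps * n_cameras


# ---------------------------------------------------------------------------
# measurement records
# ---------------------------------------------------------------------------

@dataclass
class CameraMeasurement:
    """Per-camera ellipse data of one measurement row."""

    width_px: float
    height_px: float
    center_x_px: float
    center_y_px: float
    angle_deg: float
    diameter_px: float
    circumference_px: float
    confidence: float | None = None
    outline_confidence: float = 0.0

    @classmethod
    def from_fit(cls, fit: PupilFit) -> "CameraMeasurement | None":
        if not fit.valid:
            return None
        return cls(
            width_px=fit.major_axis, height_px=fit.minor_axis,
            center_x_px=fit.center[0], center_y_px=fit.center[1],
            angle_deg=fit.angle, diameter_px=fit.diameter_px,
            circumference_px=fit.circumference_px,
            confidence=fit.algorithm_confidence,
            outline_confidence=fit.outline_confidence,
        )


@dataclass
class MeasurementRecord:
    """One CSV row: frame identity plus per-camera pupil data.

    Exactly one identity field is populated: ``timestamp_ms`` in online
    mode, ``filename`` in offline mode.  ``physical_diameter_mm`` is stereo
    only and may be missing (encoded as an empty CSV field).
    """

    filename: str | None = None
    timestamp_ms: float | None = None
    main: CameraMeasurement | None = None
    secondary: CameraMeasurement | None = None
    physical_diameter_mm: float | None = None

    def __post_init__(self):
        if (self.filename is None) == (self.timestamp_ms is None):
            raise ValueError(
                "exactly one of filename (offline) or timestamp_ms (online) "
                "must be set"
            )


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return ""
    if isinstance(value, str):
        return value
    return f"{value:.6f}"


def _cam_values(cam: CameraMeasurement | None) -> list:
    if cam is None:
        return [None] * 9
    return [cam.width_px, cam.height_px, cam.center_x_px, cam.center_y_px,
            cam.angle_deg, cam.diameter_px, cam.circumference_px,
            cam.confidence, cam.outline_confidence]


def write_records(records, path) -> None:
    """Write measurement records with the fixed header, 6-decimal floats."""
    lines = [",".join(CSV_HEADER)]
    for rec in records:
        row = (
            [rec.filename, rec.timestamp_ms]
            + _cam_values(rec.main)
            + _cam_values(rec.secondary)
            + [rec.physical_diameter_mm]
        )
        lines.append(",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_cam(fields: dict, prefix: str) -> CameraMeasurement | None:
    keys = ["width_px", "height_px", "center_x_px", "center_y_px", "angle_deg",
            "diameter_px", "circumference_px", "confidence",
            "outline_confidence"]
    vals = [fields[f"{prefix}_{k}"] for k in keys]
    if all(v is None for v in vals):
        return None
    required = vals[:7] + [vals[8]]
    if any(v is None for v in required):
        return None
    return CameraMeasurement(
        width_px=vals[0], height_px=vals[1], center_x_px=vals[2],
        center_y_px=vals[3], angle_deg=vals[4], diameter_px=vals[5],
        circumference_px=vals[6], confidence=vals[7], outline_confidence=vals[8],
    )


def read_records(path) -> list[MeasurementRecord]:
    """Read a measurement CSV (header-keyed; column order is free)."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise SchemaError("empty measurement file")
    header = [h.strip() for h in text[0].split(",")]
    unknown = set(header) - set(CSV_HEADER)
    missing = set(CSV_HEADER) - set(header)
    if unknown or missing:
        raise SchemaError(
            f"unexpected measurement schema (unknown={sorted(unknown)}, "
            f"missing={sorted(missing)})"
        )
    records = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(header):
            raise RowError(
                f"line {lineno}: expected {len(header)} fields, got {len(cells)}",
                line_number=lineno,
            )
        fields = {}
        for name, cell in zip(header, cells):
            cell = cell.strip()
            if cell == "":
                fields[name] = None
            elif name in _STR_FIELDS:
                fields[name] = cell
            else:
                try:
                    fields[name] = float(cell)
                except ValueError as exc:
                    raise RowError(
                        f"line {lineno}: non-numeric value {cell!r} in {name}",
                        line_number=lineno,
                    ) from exc
        records.append(
            MeasurementRecord(
                filename=fields["filename"],
                timestamp_ms=fields["timestamp_ms"],
                main=_parse_cam(fields, "main"),
                secondary=_parse_cam(fields, "sec"),
                physical_diameter_mm=fields["physical_diameter_mm"],
            )
        )
    return records


def records_to_frame(records):
    """Records as a DataFrame ready for :mod:`stereopupil.preprocess`."""
    import pandas as pd

    rows = []
    for i, rec in enumerate(records):
        row = {
            "frame_count": i,
            "timestamp_ms": rec.timestamp_ms,
            "diameter_mm": rec.physical_diameter_mm,
        }
        for prefix, cam in (("main", rec.main), ("secondary", rec.secondary)):
            if cam is None:
                row[f"outline_confidence_{prefix}"] = np.nan
                row[f"axis_ratio_{prefix}"] = np.nan
                row[f"diameter_px_{prefix}"] = np.nan
            else:
                row[f"outline_confidence_{prefix}"] = cam.outline_confidence
                row[f"axis_ratio_{prefix}"] = cam.height_px / cam.width_px
                row[f"diameter_px_{prefix}"] = cam.diameter_px
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file camera
# ---------------------------------------------------------------------------

_FRAME_INDEX_RE = re.compile(r"(\d+)$")
IMAGE_EXTENSIONS = {".bmp", ".tif", ".tiff", ".jpg", ".jpeg", ".png"}


def file_camera(directory, pattern: str = "*", camera_id: str = "mono",
                skipped: list | None = None):
    """Yield EyeImages from a recorded image directory, ordered by frame index.

    The frame count is the trailing integer in each filename stem (numeric
    order, so ``img_2`` precedes ``img_10``).  Files without a parsable
    index are listed in ``skipped`` (if given) and the stream continues.
    No timestamps are assigned in offline mode.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    entries = []
    for p in sorted(directory.glob(pattern)):
        if p.suffix.lower() not in IMAGE_EXTENSIONS or not p.is_file():
            continue
        m = _FRAME_INDEX_RE.search(p.stem)
        if not m:
            if skipped is not None:
                skipped.append(p.name)
            continue
        entries.append((int(m.group(1)), p))
    entries.sort(key=lambda e: e[0])
    for frame_count, p in entries:
        px = np.asarray(iio.imread(p))
        if px.ndim == 3:  # RGB -> luma
            px = np.clip(
                np.round(px[..., :3] @ np.array([0.299, 0.587, 0.114])), 0, 255
            ).astype(np.uint8)
        yield EyeImage(px, frame_count=frame_count, camera_id=camera_id,
                       source_name=p.name)
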