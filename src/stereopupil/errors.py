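"""Exception types shared across the pipeline."""


class StereoPupilError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(StereoPupilError, ValueError):
    """Geometric input is degenerate (too few / collinear points, ...)."""


class InvalidFitError(StereoPupilError, ValueError):
    """An operation requiring a valid pupil fit received an invalid one."""


class InsufficientViewsError(StereoPupilError, RuntimeError):
    """Calibration image stream was exhausted before enough pattern views."""


class ConditioningError(StereoPupilError, RuntimeError):
    """Calibration problem is underdetermined or numerically degenerate."""


class CalibrationStateError(StereoPupilError, RuntimeError):
    """A calibrated stereo rig is required but not available."""


class TriangulationDegenerateError(StereoPupilError, RuntimeError):
    """Projection rays are (near-)parallel; no stable intersection exists."""


class StreamCorruptionError(StereoPupilError, RuntimeError):
    """Frame-count bookkeeping of an image stream is inconsistent."""


class SchemaError(StereoPupilError, ValueError):
    """A measurement CSV file does not follow the expected schema."""


class RowError(StereoPupilError, ValueError):
    """A measurement CSV row is malformed."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number
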