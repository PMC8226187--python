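"""Exception types shared across the analysis layers."""


class DuetPhaseError(Exception):
    """Base class for package errors."""


class ConfigError(DuetPhaseError, ValueError):
    """Invalid configuration value (names the offending field)."""


class InsufficientDataError(DuetPhaseError, ValueError):
    """Too few samples/onsets for the requested analysis."""


class AlignmentError(DuetPhaseError, ValueError):
    """Series that must share a grid or support do not."""


class WindowError(DuetPhaseError, ValueError):
    """Analysis window too short for the sampling rate."""


class CalibrationError(DuetPhaseError, ValueError):
    """Radius calibration impossible (degenerate series)."""


class GeometryError(DuetPhaseError, ValueError):
    """Degenerate spatial configuration (e.g. coincident heads)."""


class ControllerError(DuetPhaseError, RuntimeError):
    """Virtual-agent controller produced an unusable trajectory."""


class BandError(DuetPhaseError, ValueError):
    """Requested frequency band is empty on the analysis grid."""


class DegenerateMotionError(DuetPhaseError, ValueError):
    """Motion input with no variance (rank-0)."""
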