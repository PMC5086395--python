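"""Exception hierarchy for kinetracker."""


class KinetrackerError(Exception):
    """Base class for all kinetracker errors."""


class ParameterError(KinetrackerError, ValueError):
    """An operation was called with an invalid parameter value."""


class CalibrationError(KinetrackerError):
    """The stream does not contain enough usable calibration frames."""


class DegenerateSkeletonError(KinetrackerError):
    """A body segment estimated from calibration frames is implausibly short."""


class DegenerateGeometryError(KinetrackerError, ValueError):
    """An angle was requested on coincident points / zero-length rays."""


class UndefinedMetricError(KinetrackerError):
    """A performance metric is undefined for the given events."""


class ConfigError(KinetrackerError, ValueError):
    """An exercise configuration resolved to an unusable value."""


class InputError(KinetrackerError, ValueError):
    """A signal or stream violates an input contract (e.g. non-monotone time)."""


class StreamParseError(KinetrackerError, ValueError):
    """A stream file could not be parsed; message carries the line number."""


class StreamValidationError(KinetrackerError, ValueError):
    """A parsed stream violates the skeleton-stream invariants."""


class MotionSpecError(KinetrackerError, ValueError):
    """A synthetic motion specification is kinematically inconsistent."""
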