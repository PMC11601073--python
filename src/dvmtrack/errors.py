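"""Exception hierarchy shared across the package."""


class DvmTrackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DvmTrackError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(DvmTrackError):
    """Parsed data violates a structural invariant (ordering, duplicates, signs)."""


class CalibrationError(DvmTrackError):
    """A fluorescence calibration cannot be fit (too few pairs, zero variance)."""


class StateError(DvmTrackError):
    """An operation was called on an object missing a required channel."""


class EmptyProfileError(DvmTrackError):
    """A profile has no usable (non-missing) bins."""


class DegenerateProfileError(DvmTrackError):
    """A profile is numerically degenerate (zero integral, zero mean)."""


class ConfigurationError(DvmTrackError):
    """A configuration value is invalid or missing (CFL violation, unknown key,
    missing carbon weight)."""


class UndefinedCorrelationError(DvmTrackError):
    """A correlation is undefined because one input is constant."""
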