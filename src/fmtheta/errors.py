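"""Exception types shared across the pipeline."""


class FmthetaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FmthetaError):
    """A configuration value violates its documented constraints."""


class CalibrationError(FmthetaError):
    """EOG calibration could not identify any artifact window."""


class UnprofiledSubjectError(FmthetaError):
    """No theta peak could be determined for at least one task condition."""


class FormatError(FmthetaError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(FmthetaError):
    """Parsed data violates a domain invariant (e.g. concentration > 1)."""
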