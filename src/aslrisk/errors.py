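"""Exception hierarchy for the aslrisk package."""


class AslRiskError(Exception):
    """Base class for all package errors."""


class ConfigError(AslRiskError):
    """Invalid configuration; the message names the offending field."""


class SizingError(ConfigError):
    """Grid too small to place the requested phantom structures."""


class DimensionError(AslRiskError):
    """Volumes that must share a grid do not."""


class FormatError(AslRiskError):
    """Malformed input data (e.g. an odd number of ASL frames)."""


class CalibrationError(AslRiskError):
    """CSF-based M0 calibration failed (empty mask, non-positive M0)."""


class MissingDataError(AslRiskError):
    """A required participant field is unresolvable; names the field."""


class StatsError(AslRiskError):
    """A statistical routine received an inestimable problem."""


class DataJoinError(AslRiskError):
    """Tables that must join on participant id do not; lists orphans."""
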