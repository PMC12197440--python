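"""Exception hierarchy for tlcdens.

Every invariant violation raises a named error so CLI config validation can
map failures to exit codes deterministically.
"""


class TLCError(Exception):
    """Base class for all tlcdens errors."""


class FormatError(TLCError):
    """Input raster is not the expected 8-bit RGB layout."""


class ConfigError(TLCError):
    """A configuration value violates its documented invariant."""


class GeometryError(TLCError):
    """A coordinate, crop or region falls outside its valid domain."""


class InsufficientDataError(TLCError):
    """Too few data points for the requested fit or statistic."""


class InvalidModelError(TLCError):
    """A calibration model cannot be used (e.g. non-positive slope)."""


class OutOfCalibrationError(TLCError):
    """Predicted concentration falls outside the calibrated linear range."""


class UndefinedStatError(TLCError):
    """A statistic is undefined for the given inputs (e.g. CV with zero mean)."""


class EmptyLaneError(TLCError, LookupError):
    """Principal-spot selection was asked for an empty lane."""
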