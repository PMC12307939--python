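"""Exception hierarchy.

All validation-type failures derive from :class:`BioeconError` (itself a
``ValueError``) so callers — and the CLI exit-code mapping — can distinguish
bad inputs from internal faults.
"""


class BioeconError(ValueError):
    """Base class for all input / model validation errors."""


class InvalidSizeError(BioeconError):
    """A size parameter (sector count, horizon, stream length) is out of range."""


class InvalidParameterError(BioeconError):
    """A scalar parameter is outside its admissible range."""


class DimensionError(BioeconError):
    """Arrays or label sets are dimensionally inconsistent."""


class LabelError(BioeconError):
    """A sector name is unknown, duplicated, or misaligned."""


class ZeroOutputError(BioeconError):
    """A sector has zero total output, so technical coefficients are undefined."""


class NonProductiveEconomyError(BioeconError):
    """The coefficient matrix has spectral radius >= 1 (Hawkins-Simon fails)."""


class AllocationError(BioeconError):
    """Investment allocation weights are invalid (negative or not summing to 1)."""


class MissingClosureError(BioeconError):
    """Type II closure requested without household data."""


class UndefinedSharesError(BioeconError):
    """Sector shares requested for an all-zero impact vector."""


class InfeasibleAnchorsError(BioeconError):
    """Calibration anchors incompatible with a nonnegative benefit stream."""


class InvalidRateError(BioeconError):
    """Discount or growth rate <= -1."""


class InvalidSpreadError(BioeconError):
    """Cost-spreading window longer than the appraisal horizon."""


class UndefinedRatioError(BioeconError):
    """Benefit-cost ratio requested with zero discounted cost."""


class MissingSectionError(BioeconError):
    """A report section required by the renderer is absent."""


class SchemaError(BioeconError):
    """A report document does not conform to the shipped schema."""
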