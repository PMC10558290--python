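"""Exception hierarchy shared across the package.

``ValidationError`` subclasses ``ValueError`` so callers that catch the
builtin still work; the CLI maps any ``CensusError`` to exit code 2.
"""


class CensusError(Exception):
    """Base class for all errors raised by abpcensus."""


class ValidationError(CensusError, ValueError):
    """Invalid input values or configuration."""


class InvalidConstantsError(ValidationError):
    """Cell constants violate their positivity/range invariants."""


class DegenerateDesignError(ValidationError):
    """A regression design with too few points or zero predictor variance."""


class OutOfLinearRangeError(CensusError):
    """A lysate band falls outside the standard curve's interpolation range."""


class BelowCalibrationError(CensusError):
    """A fluorescence signal below the calibration line's intercept."""


class UndefinedFractionError(CensusError):
    """Cytosolic fraction undefined (empty cytosol region or non-positive cell mean)."""


class IntegrityError(CensusError):
    """Packaged reference data failed an integrity check."""
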