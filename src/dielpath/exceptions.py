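"""Exception hierarchy shared across the package."""


class DielPathError(Exception):
    """Base class for all package errors."""


class SchemaError(DielPathError):
    """Input table does not carry the required columns."""


class IntegrityError(DielPathError):
    """Duplicate or internally inconsistent records in an input table."""


class CoverageError(DielPathError):
    """Environmental records do not cover the requested sampling window."""


class AlignmentError(DielPathError):
    """Series supplied to a joint fit do not share a sampling grid."""


class IdentifiabilityError(DielPathError):
    """Too few timepoints (or degenerate inputs) to identify the model."""


class StandardizationError(DielPathError):
    """An exogenous column is constant and cannot be z-scored."""


class ExtrapolationError(DielPathError):
    """Prediction requested outside the fitted trend's time-of-day span."""


class StabilityError(DielPathError):
    """A simulated trajectory left its admissible domain."""


class ConvergenceError(DielPathError):
    """MCMC chains failed the convergence diagnostic."""


class CycleError(DielPathError):
    """A series is too short to define at least two diel cycles."""


class LengthError(DielPathError):
    """A series is too short for the requested embedding."""


class LibraryError(DielPathError):
    """A cross-map library is smaller than the embedding requires."""
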