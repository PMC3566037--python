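"""Exception hierarchy for the capacity-load pipeline.

Every stage raises a subclass of :class:`CapLoadError` so drivers can abort
with stage-named diagnostics rather than bare numpy/pandas errors.
"""


class CapLoadError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(CapLoadError):
    """Input table does not match the documented column dictionary."""


class AgeRangeError(CapLoadError):
    """Requested age falls outside the reference grid (no extrapolation)."""


class DomainError(CapLoadError):
    """Measurement or parameter outside its mathematical domain."""


class InsufficientDataError(CapLoadError):
    """Too few records for the requested operation (e.g. n < p + 2)."""


class DegenerateGeometryError(CapLoadError):
    """Singular covariance in the outlier search (collinear columns)."""


class DegenerateFitError(CapLoadError):
    """Regression with zero residual variance or zero regressor variance."""


class StratumError(CapLoadError):
    """A sex stratum is empty or below the minimum size."""


class CollinearityError(CapLoadError):
    """Rank-deficient design matrix in a model fit."""


class SeparationError(CapLoadError):
    """Complete or quasi-complete separation in a logistic fit."""


class ClassError(CapLoadError):
    """A logistic outcome class is empty."""


class CalibrationError(CapLoadError):
    """Generator configuration implies an infeasible variance decomposition."""
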