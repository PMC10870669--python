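"""Exception hierarchy shared across the package."""


class ElndiError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ElndiError, ValueError):
    """A value violates an operation's precondition (e.g. non-finite input)."""


class SchemaError(ElndiError):
    """Cohort columns and the variable dictionary disagree, or required columns are absent."""


class ConfigurationError(ElndiError):
    """A configuration object is internally inconsistent or infeasible for the data."""


class StratificationError(ElndiError):
    """A stratified split or cross-validation fold cannot hold both outcome classes."""


class InsufficientControlsError(ElndiError):
    """Balanced-cohort construction needs at least as many controls as cases."""


class UnimputableRecordError(ElndiError):
    """A subject has no observed cell, so no neighbour distance is defined."""


class UndefinedMetricError(ElndiError):
    """A diagnostic metric is undefined for the given confusion matrix or labels."""


class ConvergenceError(ElndiError):
    """Iterative calibration or fitting failed to converge."""
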