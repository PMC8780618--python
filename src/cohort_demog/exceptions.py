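"""Exception hierarchy shared across the package.

``ValidationError`` subclasses map to CLI exit code 2, ``NumericError``
subclasses to exit code 3.
"""


class CohortDemogError(Exception):
    """Base class for all package errors."""


class ValidationError(CohortDemogError):
    """Invalid inputs, files, or configuration."""


class SampleSizeError(ValidationError):
    """Too few observations for the requested analysis."""


class DegenerateSampleError(ValidationError):
    """Sample with zero variance where spread is required."""


class ConfigurationError(ValidationError):
    """Unusable analysis settings (e.g. too few bootstrap replicates)."""


class ClassificationError(ValidationError):
    """Instar boundaries that leave a class empty or are ill-ordered."""


class EmptyCohortError(ValidationError):
    """No usable female records in a cohort."""


class NumericError(CohortDemogError):
    """Numerical failure (root bracketing, undefined quantity)."""


class ResolutionError(NumericError):
    """Density curve cannot resolve the requested number of modes."""


class SolverError(NumericError):
    """Root finder failed to bracket or converge."""
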