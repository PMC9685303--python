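"""Exception hierarchy shared across the package."""


class YpstageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(YpstageError, ValueError):
    """Invalid simulation configuration; message names the offending field."""


class SchemaError(YpstageError, ValueError):
    """Malformed cohort file; message cites the offending row where known."""


class DomainError(YpstageError, ValueError):
    """Input outside the documented domain of an operation."""


class CalibrationError(YpstageError, ValueError):
    """Survival anchors that no piecewise-exponential baseline can reach."""


class ConvergenceError(YpstageError, RuntimeError):
    """Partial-likelihood maximisation failed (e.g. monotone likelihood)."""


class RankError(YpstageError, RuntimeError):
    """Singular information matrix or too few events for the design."""


class UndefinedResultError(YpstageError, ValueError):
    """A statistic is undefined for the given data (e.g. no comparable pairs)."""


class EvaluationError(YpstageError, ValueError):
    """A staging system cannot be scored on this cohort (e.g. one group)."""


class AssemblyError(YpstageError, ValueError):
    """A merge result cannot be turned into a valid staging system."""
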