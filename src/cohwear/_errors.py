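"""Exception hierarchy for the cohwear package."""


class CohwearError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CohwearError):
    """A file could not be parsed (e.g. malformed timestamp); names the row."""


class ValidationError(CohwearError):
    """Input violated a structural invariant (duplicate/non-monotone timestamps, bounds)."""


class DegenerateBaselineError(CohwearError):
    """A baseline stratum has zero variance, so z-scores are undefined."""


class InsufficientBaselineError(CohwearError):
    """A baseline stratum has fewer resting minutes than required."""


class UndefinedStatisticError(CohwearError):
    """A statistic is undefined for the given input (constant series, single-class ROC)."""


class NotComputableError(CohwearError):
    """A summary could not be computed because no qualifying data exist."""
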