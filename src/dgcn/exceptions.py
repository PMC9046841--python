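"""Exception hierarchy for the dgcn package."""


class DgcnError(Exception):
    """Base class for all dgcn errors."""


class InvalidInputError(DgcnError, ValueError):
    """Malformed data passed to an operation (bad shape, non-finite values)."""


class ConfigurationError(DgcnError, ValueError):
    """Inconsistent or unusable configuration (dimension mismatch, empty
    transform family, non-positive margin...)."""


class InsufficientDataError(DgcnError, ValueError):
    """Not enough samples to perform the requested operation."""


class DegenerateGraphError(DgcnError, ValueError):
    """A graph with a zero-degree node reached symmetric normalization."""


class UndefinedStatisticError(DgcnError, ZeroDivisionError):
    """A ratio statistic was requested with a zero denominator."""


class NumericError(DgcnError, ArithmeticError):
    """A non-finite value appeared where a finite one is required."""
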