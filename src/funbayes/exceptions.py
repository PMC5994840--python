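"""Exception hierarchy shared across the package."""


class FunBayesError(Exception):
    """Base class for all funbayes errors."""


class ParameterError(FunBayesError, ValueError):
    """Invalid parameter value (bad knot count, period <= 0, ...)."""


class DimensionError(FunBayesError, ValueError):
    """Shape mismatch between arrays that must conform."""


class DomainError(FunBayesError, ValueError):
    """Evaluation requested outside the domain of a basis system."""


class ConditioningError(FunBayesError, ValueError):
    """A linear system is numerically rank deficient / ill conditioned."""


class DataError(FunBayesError, ValueError):
    """Invalid data values (non-finite entries, missing cells, ...)."""


class ContractError(FunBayesError, TypeError):
    """An operation was called on an object that cannot support it."""
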