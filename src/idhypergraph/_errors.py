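"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: SchemaError/ConfigError -> 2,
NumericalError -> 3, everything else propagates.
"""


class IDHypergraphError(Exception):
    """Base class for all package errors."""


class InvalidInputError(IDHypergraphError, ValueError):
    """Malformed or out-of-contract input (bad indices, NaNs, ranges)."""


class DegenerateInputError(InvalidInputError):
    """Input that makes a quantity undefined (e.g. zero-norm vector)."""


class ConfigError(IDHypergraphError, ValueError):
    """Invalid run configuration."""


class SchemaError(IDHypergraphError, ValueError):
    """Input table does not match the expected schema."""


class ConvergenceError(IDHypergraphError, RuntimeError):
    """Iterative solver failed to converge; carries its trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class NumericalError(IDHypergraphError, ArithmeticError):
    """Non-finite or otherwise broken numerical state."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


class UndefinedMetricError(IDHypergraphError, ZeroDivisionError):
    """A requested classification metric has a zero denominator."""


class DesignError(IDHypergraphError, ValueError):
    """Rank-deficient regression design; lists the aliased columns."""

    def __init__(self, message: str, aliased=None):
        super().__init__(message)
        self.aliased = aliased or []
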