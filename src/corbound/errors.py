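"""Exception hierarchy for corbound.

All positions quoted in error messages are 1-based (row, column), matching
the user-facing convention of the rest of the package.
"""


class CorboundError(ValueError):
    """Base class for all corbound errors."""


class DimensionError(CorboundError):
    """Input matrix is not square, or dimensions of two inputs disagree."""


class ValidityError(CorboundError):
    """A matrix fails one of the correlation-matrix validity conditions."""


class DecompositionError(CorboundError):
    """Cholesky factorization hit a negative pivot (matrix not PSD)."""


class MissingPatternError(CorboundError):
    """The pattern of missing entries is not the one an operation requires."""


class InfeasibleError(CorboundError):
    """No value of the missing correlation yields a valid matrix."""


class SpecificationError(CorboundError):
    """An imputation distribution specification is inconsistent."""


class PoolingError(CorboundError):
    """A pooled cell is observed in zero studies under an estimator that needs data."""
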