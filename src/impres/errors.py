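"""Exception hierarchy shared across the package."""


class ImpresError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ImpresError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(ImpresError, ValueError):
    """A trial log or stimulus table failed validation; the message names the row."""


class DegenerateDataError(ImpresError, ValueError):
    """The data carry no usable signal (zero variance, all-zero dissimilarities, ...)."""


class NumericalError(ImpresError, ArithmeticError):
    """An iterative fit produced non-finite values or failed to converge."""
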