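"""Exception hierarchy shared across the package."""


class BlastonetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BlastonetError, ValueError):
    """A function argument is outside its documented domain."""


class InvalidMeshError(BlastonetError, ValueError):
    """A mesh violates its structural invariants (open surface, zero volume...)."""


class InvalidVectorError(BlastonetError, ValueError):
    """A degree-count vector is non-graphical or has the wrong length."""


class InvalidInputError(BlastonetError, ValueError):
    """Inconsistent collection-level input (e.g. mixed network sizes)."""


class ConvergenceError(BlastonetError, RuntimeError):
    """An iterative procedure failed to converge within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GradeParseError(BlastonetError, ValueError):
    """A Gardner grade string could not be parsed."""


class InsufficientDataError(BlastonetError, ValueError):
    """A statistical routine received degenerate samples."""


class UndefinedCorrelationError(BlastonetError, ValueError):
    """Correlation is undefined (constant sample)."""


class DegenerateLabelsError(BlastonetError, ValueError):
    """A classifier was asked to fit labels containing a single class."""
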