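"""Exception hierarchy shared across the package."""


class FrtError(Exception):
    """Base class for all package errors."""


class SheetValidationError(FrtError):
    """A response sheet violates a structural invariant."""


class DomainError(FrtError):
    """A covariate lies outside the domain of its transform."""


class InsufficientSampleError(FrtError):
    """Sample too small for the requested nonparametric limit."""

    def __init__(self, message: str, minimum_n: int | None = None):
        super().__init__(message)
        self.minimum_n = minimum_n


class DegenerateSampleError(FrtError):
    """Sample has no spread; tolerance bands are undefined."""


class SchemaError(FrtError):
    """Tabular input does not match the documented dialect."""
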