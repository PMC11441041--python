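"""Exception types shared across the package."""


class MVTeerError(Exception):
    """Base class for all package errors."""


class ParameterError(MVTeerError, ValueError):
    """An input parameter violates its documented contract."""


class GeometryError(MVTeerError):
    """A mesh or landmark set violates a geometric invariant."""


class SchemaError(MVTeerError):
    """A file does not conform to the expected on-disk schema."""


class NumericalError(MVTeerError):
    """A numerical operation encountered a degenerate configuration."""


class ConvergenceError(MVTeerError):
    """An iterative solve failed to reach its tolerance.

    Carries the residual / distance history for diagnosis.
    """

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []
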