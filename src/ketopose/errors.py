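"""Exception hierarchy shared across the package."""


class KetoposeError(Exception):
    """Base class for all package errors."""


class ParseError(KetoposeError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(KetoposeError):
    """Input violates a structural invariant (duplicate atoms, roster mismatch)."""


class ValidationError(KetoposeError):
    """A parameter or input fails its precondition."""


class AtomLookupError(KetoposeError, KeyError):
    """A named atom is absent from a structure; the message names the atom."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return Exception.__str__(self)


class DegenerateGeometryError(KetoposeError):
    """Geometry too close to degenerate (coplanar/collinear) to classify."""


class ConvergenceError(KetoposeError):
    """An iterative solver failed to reach tolerance; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigError(KetoposeError):
    """Pipeline configuration is invalid (unknown stage, missing input...)."""
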