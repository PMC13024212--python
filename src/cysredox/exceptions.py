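"""Exception hierarchy for cysredox."""


class CysredoxError(Exception):
    """Base class for all package errors."""


class ValidationError(CysredoxError, ValueError):
    """A parameter or state failed validation; the message names the field."""


class IntegrationError(CysredoxError, RuntimeError):
    """The ODE solver failed; carries the model time at failure."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class MappingError(CysredoxError, KeyError):
    """An observable mapping referenced an unknown metabolite or flux term."""


class CalibrationError(CysredoxError, RuntimeError):
    """All optimisation starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NotIdentifiableError(CysredoxError, ValueError):
    """A quantity is structurally not identifiable from the given inputs."""


class GenerationError(CysredoxError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class ClassificationError(CysredoxError, RuntimeError):
    """Regime classification refused (e.g. too few converged scan points)."""


class ParseError(CysredoxError, ValueError):
    """A delimited table failed to parse; the message names the row."""
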