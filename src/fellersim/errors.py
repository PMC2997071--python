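"""Exception hierarchy.

All package errors derive from :class:`FellerSimError` so callers (and the
CLI) can distinguish modelling errors from programming errors.
"""


class FellerSimError(Exception):
    """Base class for all fellersim errors."""


class ParameterError(FellerSimError, ValueError):
    """A Lévy-component parameter violates its admissibility constraint."""


class ConstructionError(FellerSimError, ValueError):
    """A family cannot be built: mixer, region or parameter-field constraint
    violated.  Carries the offending state when one exists."""

    def __init__(self, message: str, *, state: float | None = None):
        super().__init__(message)
        self.state = state


class SimulationError(FellerSimError, RuntimeError):
    """A constraint violation encountered while iterating a path."""

    def __init__(self, message: str, *, step: int | None = None,
                 state: float | None = None):
        super().__init__(message)
        self.step = step
        self.state = state


class NumericalError(FellerSimError, ArithmeticError):
    """A numerical procedure failed its tolerance; ``payload`` holds
    diagnostic values."""

    def __init__(self, message: str, *, payload: dict | None = None):
        super().__init__(message)
        self.payload = payload or {}


class UnsupportedLawError(FellerSimError, ValueError):
    """The requested diagnostic needs moments the law does not possess."""
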