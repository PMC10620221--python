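"""Exception hierarchy shared across the pipeline stages."""


class InflamnetError(Exception):
    """Base class for all package errors."""


class SifParseError(InflamnetError):
    """A SIF line could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class NetworkValidationError(InflamnetError):
    """A network violates a structural invariant."""


class ConvergenceError(InflamnetError):
    """Iterative solver failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


class FitError(InflamnetError):
    """Standard-curve fitting failed (degenerate data or optimizer failure)."""


class CurveNotAcceptedError(InflamnetError):
    """Refusal to back-calculate concentrations from a rejected curve."""


class MissingControlError(InflamnetError):
    """A normalization control is absent; names the orphan group."""


class ScenarioError(InflamnetError):
    """A synthetic-data scenario is infeasible as parameterized."""


class StageError(InflamnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
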