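"""Exception hierarchy shared across the package."""


class SynbathError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SynbathError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateNormalizationError(InvalidInputError):
    """Papaverine reference coincides with the precontraction plateau."""


class NoFitError(SynbathError):
    """Data carry no fittable signal (e.g. flat responses)."""


class ConvergenceError(SynbathError):
    """Least-squares optimisation failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PairingError(SynbathError):
    """Replicates cannot be matched by subject."""


class InsufficientDataError(SynbathError):
    """Fewer replicates than the statistic requires."""


class UndefinedCorrelationError(SynbathError):
    """Correlation undefined (zero variance or too few pairs)."""


class SchemaError(SynbathError):
    """A tidy table does not conform to the documented CSV schema."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


class PipelineError(SynbathError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
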