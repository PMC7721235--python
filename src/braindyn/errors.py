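"""Exception hierarchy shared across the pipeline."""


class BraindynError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BraindynError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(BraindynError, ValueError):
    """Input is structurally valid but statistically degenerate (e.g. zero variance)."""


class AlignmentError(BraindynError, ValueError):
    """Region labels or dimensions of two objects do not match."""


class DivergenceError(BraindynError, RuntimeError):
    """A numerical integration produced non-finite state."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class GenerationError(BraindynError, RuntimeError):
    """Synthetic-cohort generation failed; carries seed and subject id."""

    def __init__(self, message: str, seed=None, subject_id=None):
        super().__init__(message)
        self.seed = seed
        self.subject_id = subject_id


class BalanceFailureError(BraindynError, RuntimeError):
    """Age-balanced splitting exhausted its retry budget."""

    def __init__(self, message: str, best_p: float | None = None):
        super().__init__(message)
        self.best_p = best_p


class EstimationFailureError(BraindynError, RuntimeError):
    """Parameter estimation could not produce a usable run."""


class InsufficientReplicatesError(BraindynError, ValueError):
    """Fewer replicate parameter sets than a group comparison requires."""


class UndefinedMetricError(BraindynError, ValueError):
    """A normalized graph metric is undefined (e.g. zero null clustering)."""
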