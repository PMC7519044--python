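"""Exception types shared across the package."""


class GaitWomacError(Exception):
    """Base class for all package errors."""


class ValidationError(GaitWomacError, ValueError):
    """Raised when an input violates a documented precondition."""


class UndefinedStatisticError(GaitWomacError, ArithmeticError):
    """Raised when a statistic is undefined for the given input
    (e.g. kurtosis of a zero-variance sequence, peak2rms of the zero signal)."""


class PipelineError(GaitWomacError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name and a code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
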