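"""Exception types shared across the package."""


class RicewalkError(Exception):
    """Base class for all ricewalk errors."""


class DataError(RicewalkError, ValueError):
    """Malformed, empty, or otherwise unusable input data."""


class ConvergenceError(RicewalkError, RuntimeError):
    """Iteration budget exhausted before the stopping rule was met."""

    def __init__(self, message: str, last_delta: float, iterations: int):
        super().__init__(message)
        self.last_delta = last_delta
        self.iterations = iterations
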