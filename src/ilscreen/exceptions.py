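"""Exception hierarchy used across the package."""


class IlscreenError(Exception):
    """Base class for all package errors."""


class FormatError(IlscreenError):
    """A file does not conform to the expected dialect (missing columns, empty file)."""


class ValidationError(IlscreenError):
    """Input data violates a model invariant (negative areas, charge 0, bad fractions)."""


class GridMismatchError(ValidationError):
    """Two profiles that must share a sigma grid do not."""


class ConvergenceError(IlscreenError):
    """The segment self-consistency iteration did not reach tolerance.

    Carries the last residual (max |dmu|/RT) and the iteration count so callers
    can report or retry with different solver settings.
    """

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations
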