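"""Exception hierarchy shared by all burstfish modules.

Everything derives from :class:`BurstfishError` so callers can catch the
package's failures with a single except clause; each subclass also inherits
the closest builtin (ValueError/RuntimeError) so idiomatic handling works.
"""


class BurstfishError(Exception):
    """Base class for all burstfish errors."""


class InvalidParameterError(BurstfishError, ValueError):
    """Kinetic parameters are non-positive or non-finite."""


class ArgumentError(BurstfishError, ValueError):
    """A function argument is out of its documented domain."""


class UndefinedRatioError(BurstfishError, ZeroDivisionError):
    """Active/inactive ratio requested with zero empty cells."""


class FitFailureError(BurstfishError, RuntimeError):
    """Optimizer failed to converge from every start."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class BoundaryFitError(FitFailureError):
    """Degenerate input pins the fit to the edge of parameter space."""


class InsufficientDataError(BurstfishError, ValueError):
    """Too few histogram bins (or lanes) for the requested statistic."""


class CalibrationError(BurstfishError, ValueError):
    """Single-transcript calibration is empty or degenerate."""


class GatingError(BurstfishError, ValueError):
    """Cell gating produced an unusable population."""


class StructureError(BurstfishError, ValueError):
    """Band-count table is missing the control template or input lane."""


class NonFiniteValueError(BurstfishError, ValueError):
    """A computation produced inf/nan; usually fixed by a pseudocount."""


class ResourceError(BurstfishError, RuntimeError):
    """Requested simulation exceeds the configured event budget."""


class NumericalError(BurstfishError, RuntimeError):
    """Quadrature or series evaluation failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ParseError(BurstfishError, ValueError):
    """Malformed input file; carries the offending row when known."""

    def __init__(self, message, row=None):
        super().__init__(message)
        self.row = row


class StageError(BurstfishError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage, message):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
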