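"""Exception hierarchy.

The CLI maps these onto exit codes: argument/validation errors exit 2,
data errors exit 3, fit failures exit 4.
"""


class PhaseKitError(Exception):
    """Base class for all phasekit errors."""


class ArgumentError(PhaseKitError, ValueError):
    """Invalid argument or configuration value (CLI exit code 2)."""


class DataError(PhaseKitError):
    """Malformed or degenerate input data (CLI exit code 3)."""


class ParseError(DataError):
    """File could not be parsed; message carries the offending line number."""


class GenerationError(DataError):
    """A synthetic generator could not satisfy its constraints.

    The message names the parameter that made generation infeasible
    (e.g. a droplet packing fraction too high for rejection placement).
    """


class FitError(PhaseKitError):
    """A nonlinear fit failed to converge (CLI exit code 4).

    Carries the initialization used and the residual sum of squares at the
    point of failure so the caller can diagnose the trace.
    """

    def __init__(self, message, init=None, rss=None):
        super().__init__(message)
        self.init = init
        self.rss = rss
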