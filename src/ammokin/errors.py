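"""Exception and warning hierarchy.

Errors distinguish physically impossible measurements (sampling or labeling
faults) from configuration mistakes and from mathematically undefined
requests, so callers such as the CLI can map them to distinct exit codes.
"""


class AmmokinError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(AmmokinError):
    """A measurement pair is physically impossible (e.g. outlet > inlet)."""


class UndefinedExtractionError(AmmokinError):
    """Extraction cannot be computed (zero inlet concentration)."""


class InconsistencyError(AmmokinError):
    """Mutually contradictory kinetic quantities (e.g. clearance > blood flow)."""


class UnreachableTargetError(AmmokinError):
    """Target concentration lies at or below the generation steady state."""


class NoSteadyStateError(AmmokinError):
    """No finite steady state exists (zero clearance with ongoing generation)."""


class InsufficientDataError(AmmokinError):
    """Too few usable samples for the requested estimate."""


class DegenerateIntervalError(AmmokinError):
    """A time interval of zero length where a rate is required."""


class ConfigurationError(AmmokinError):
    """Invalid or incomplete configuration (setup menu, resolver, plan)."""


class MeasurementParseError(AmmokinError):
    """A measurement file could not be parsed.

    Carries the 1-based file line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class KineticsWarning(UserWarning):
    """Base class for package warnings."""


class DegenerateInputWarning(KineticsWarning):
    """Degenerate but tolerated input (e.g. start already at/below target)."""


class ClippedClearanceWarning(KineticsWarning):
    """A fitted clearance was negative and clipped to zero."""


class NegativeGenerationWarning(KineticsWarning):
    """An estimated generation rate is negative (net removal off dialysis)."""
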