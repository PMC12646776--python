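"""Exception hierarchy for epigame.

All errors derive from :class:`EpigameError` so callers can catch the
package's failures with a single except clause.
"""


class EpigameError(Exception):
    """Base class for all epigame errors."""


class ParameterError(EpigameError, ValueError):
    """A scalar parameter or argument is outside its validity range."""


class StateError(EpigameError, ValueError):
    """A state matrix or agent configuration violates its invariants."""


class ParseError(EpigameError, ValueError):
    """A text input file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyNetworkError(EpigameError, ValueError):
    """An operation produced or received a network with no nodes."""


class DegenerateThresholdError(EpigameError, ValueError):
    """The contact graph has no edges, so the spectral radius is zero."""


class SelectionExhaustionError(EpigameError, RuntimeError):
    """Seed selection could not collect K distinct seeds in bounded attempts."""


class CapacityError(EpigameError, ValueError):
    """An exact-enumeration routine was asked for a state space that is too large."""
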