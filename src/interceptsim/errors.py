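"""Exception hierarchy.

Exit-code mapping for the CLI: :class:`ConfigurationError` -> 2,
:class:`DataError` -> 3.
"""


class InterceptSimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(InterceptSimError, ValueError):
    """A scalar argument violates its precondition (e.g. non-positive velocity)."""


class ConfigurationError(InterceptSimError):
    """A config file or parameter set is inconsistent or infeasible."""


class DataError(InterceptSimError):
    """Input data violate the documented schema or invariants."""


class TooShortError(DataError):
    """Trace shorter than the filter warm-up / minimum length."""


class NoMovementError(DataError):
    """Velocity never exceeds the movement floor; no reach present."""


class NoCrossingError(DataError):
    """The effector never crossed the strike-zone center line."""
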