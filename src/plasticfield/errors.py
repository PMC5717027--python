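"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`PlasticFieldError`, so callers can catch the whole family at once.
"""


class PlasticFieldError(Exception):
    """Base class for all errors raised by plasticfield."""


class InvalidInputError(PlasticFieldError, ValueError):
    """An argument violates a documented precondition (non-finite stimulus,
    dimension mismatch, negative density, ...)."""


class SingularTimeError(PlasticFieldError):
    """An operation that divides by the landscape time was attempted at
    time zero (V = U/t is undefined at t = 0)."""


class StabilityError(PlasticFieldError):
    """A numerical integration diverged; typically the step size is too
    large for the chosen coefficients."""


class EmptyResultError(PlasticFieldError):
    """A search finished with nothing to report (e.g. no restart of the
    minima search converged)."""


class FormatError(InvalidInputError):
    """A file could not be parsed in the expected format."""


class ConfigError(PlasticFieldError):
    """A configuration mapping is missing required keys or holds values of
    the wrong type.  ``keys`` lists the offending entries."""

    def __init__(self, message: str, keys: list[str] | None = None):
        super().__init__(message)
        self.keys = list(keys or [])
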