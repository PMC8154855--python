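"""Exception hierarchy.

All package errors derive from :class:`SpinPathError` so callers can catch one
base class; validation errors also derive from :class:`ValueError` to behave
like ordinary bad-argument failures.
"""


class SpinPathError(Exception):
    """Base class for all spinpath errors."""


class ValidationError(SpinPathError, ValueError):
    """Invalid parameter or argument value."""


class FormatError(SpinPathError):
    """A file does not parse as the expected format."""


class TaggingError(SpinPathError, KeyError):
    """A required site tag is missing or cannot be resolved."""


class GeometryError(SpinPathError):
    """Degenerate geometry (e.g. collinear plane atoms)."""


class NoPathError(SpinPathError):
    """Donor and acceptor are not connected in the coupling graph."""


class DegenerateInputError(SpinPathError, ValueError):
    """An input that makes the requested quantity undefined (zero denominator,
    reducible rate matrix, ...)."""


class InsufficientDataError(SpinPathError, ValueError):
    """Too few usable data points for a fit."""


class ConfigError(SpinPathError, ValueError):
    """Invalid or unknown configuration key/value."""
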