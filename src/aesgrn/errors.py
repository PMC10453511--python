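"""Exception hierarchy shared across the package.

All errors derive from :class:`AesgrnError` so callers can catch the
package's failures with one clause; the CLI maps them to exit codes.
"""


class AesgrnError(Exception):
    """Base class for all package errors."""


class FormatError(AesgrnError, ValueError):
    """A file does not follow the expected on-disk dialect."""


class ConsistencyError(AesgrnError, ValueError):
    """Inputs that must agree (gene headers, shapes) do not."""


class DataError(AesgrnError, ValueError):
    """Data violate a precondition (too short, single-class labels, ...)."""


class SpecError(AesgrnError, ValueError):
    """An agent spec or perturbation spec is outside the allowed space."""


class NumericError(AesgrnError, ArithmeticError):
    """Training or simulation produced non-finite values."""
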