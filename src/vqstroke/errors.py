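"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`ConfigurationError` -> 2,
:class:`DataError` -> 1. Argument misuse inside the library raises plain
``ValueError`` (programming errors, not user data problems).
"""


class VQStrokeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VQStrokeError):
    """Invalid configuration value; the message names the offending field."""


class DataError(VQStrokeError):
    """Input data violates a precondition (empty class, single-class labels, ...)."""


class DomainError(VQStrokeError):
    """An image or matrix is in the wrong value domain for the operation."""
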