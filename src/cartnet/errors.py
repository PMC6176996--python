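"""Exception hierarchy.

All package-specific failures derive from :class:`CartnetError` so callers
can distinguish user/data errors from genuine bugs.
"""


class CartnetError(Exception):
    """Base class for all cartnet errors."""


class ConfigurationError(CartnetError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(CartnetError):
    """An input table violates the expected schema or its invariants."""


class NormalizationError(CartnetError):
    """A normalization step cannot proceed (e.g. missing spike-in in a sample)."""
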