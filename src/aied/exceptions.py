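"""Exception types raised across the package."""


class AiedError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AiedError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(AiedError):
    """An input table has a value that violates its contract (e.g. a negative count)."""


class ConfigurationError(AiedError):
    """A configuration object is internally inconsistent or degenerate."""


class AmbiguityError(AiedError):
    """A record cannot be interpreted without information it does not carry."""
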