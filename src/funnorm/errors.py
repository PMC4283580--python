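"""Exception hierarchy shared across the package."""


class FunnormError(Exception):
    """Base class for all package errors."""


class FormatError(FunnormError, ValueError):
    """A file or table does not have the expected structure."""


class ValidationError(FunnormError, ValueError):
    """Data violate a documented invariant."""


class ConfigurationError(FunnormError, ValueError):
    """A configuration is inconsistent or cannot be satisfied by the data."""
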