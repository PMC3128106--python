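"""Exception hierarchy shared across the package."""


class LipidgenError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LipidgenError, ValueError):
    """An input value is outside the mathematically valid domain."""


class SchemaError(LipidgenError, ValueError):
    """A table is missing required columns or contains malformed rows."""


class ConfigurationError(LipidgenError, ValueError):
    """A scenario or run configuration is internally inconsistent."""
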