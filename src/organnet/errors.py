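"""Exception types shared across the package."""


class OrgannetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OrgannetError):
    """Invalid simulation or pipeline configuration."""


class DataError(OrgannetError):
    """Malformed or inconsistent input data."""
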