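"""Exception hierarchy shared across the package."""


class EsnacchipError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EsnacchipError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(EsnacchipError):
    """Parsed data violates a domain invariant (negative intensity, bad strand, ...)."""


class ConfigError(EsnacchipError):
    """A run configuration is malformed or inconsistent."""
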