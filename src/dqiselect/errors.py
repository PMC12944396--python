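"""Exception types shared across the package."""


class DQISelectError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DQISelectError, ValueError):
    """Structurally invalid data: mismatched lengths, bad labels, missing fields."""


class ConfigurationError(DQISelectError, ValueError):
    """Inconsistent or unsupported settings."""


class SizingError(DQISelectError, ValueError):
    """Input too short or too small for the requested operation."""
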