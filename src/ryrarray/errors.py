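"""Exception hierarchy for ryrarray."""


class RyrArrayError(Exception):
    """Base class for all ryrarray errors."""


class InvalidInputError(RyrArrayError):
    """Raised for non-finite, out-of-range or otherwise malformed inputs."""


class InsufficientDataError(RyrArrayError):
    """Raised when an operation needs more data than was supplied."""


class DegenerateGeometryError(RyrArrayError):
    """Raised for point sets with no well-defined planar extent."""


class SchemaError(RyrArrayError):
    """Raised when a table does not match its declared schema."""


class ConfigurationError(RyrArrayError):
    """Raised when a required configuration value is missing or invalid."""


class GenerationError(RyrArrayError):
    """Raised when a synthetic layout cannot be realised."""
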