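"""Exception hierarchy.

Validation problems (bad names, bad schemas, bad parameters) and numerical
failures are kept distinct so the CLI can map them to different exit codes.
"""


class SomasimError(Exception):
    """Base class for all package errors."""


class ValidationError(SomasimError):
    """Bad user input: unknown names, malformed paths, schema violations."""


class RegistryError(ValidationError):
    """Unknown or duplicate component type."""


class NamingError(ValidationError):
    """Duplicate or malformed component label."""


class LookupError_(ValidationError):
    """A referenced component does not exist."""


class PathError(ValidationError):
    """Malformed or unresolvable component path."""


class ShapeError(ValidationError):
    """A state vector does not match the model layout."""


class ConfigError(ValidationError):
    """Invalid simulation configuration."""


class IntegrationError(SomasimError):
    """Non-finite state encountered during integration."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
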