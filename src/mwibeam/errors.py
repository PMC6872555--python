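"""Exception types shared across the package."""


class MWIBeamError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MWIBeamError, ValueError):
    """An input configuration violates a documented constraint."""


class ShapeError(MWIBeamError, ValueError):
    """Array shapes are inconsistent with each other or with metadata."""


class FormatError(MWIBeamError, ValueError):
    """A persisted file is malformed, incomplete or internally inconsistent."""
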