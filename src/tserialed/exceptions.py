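"""Exception hierarchy shared across the processing stages."""


class TSerialEDError(Exception):
    """Base class for all package-specific errors."""


class InvalidCellError(TSerialEDError, ValueError):
    """Unit-cell parameters do not describe a positive-definite lattice."""


class InvalidArgumentError(TSerialEDError, ValueError):
    """An argument violates a documented precondition."""


class UnsupportedFormatError(TSerialEDError, ValueError):
    """Unknown frame-container format tag."""


class FrameParseError(TSerialEDError, IOError):
    """A frame file is truncated or structurally inconsistent."""


class DataIntegrityError(TSerialEDError, ValueError):
    """Acquisition metadata is internally inconsistent (e.g. duplicate visits)."""


class InsufficientDataError(TSerialEDError, ValueError):
    """Too few observations for the requested operation."""


class IndexingFailureError(TSerialEDError):
    """No candidate basis indexes enough of the reciprocal cloud.

    Datasets raising this are counted as unindexed, not dropped silently.
    """


class ConfigurationError(TSerialEDError, ValueError):
    """Missing or inconsistent pipeline configuration."""
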