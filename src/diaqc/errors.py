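"""Exception hierarchy shared across the package."""


class DiaqcError(Exception):
    """Base class for all package errors."""


class FormatError(DiaqcError):
    """Input file is not parseable in the declared format."""


class SchemaError(DiaqcError):
    """A required column or field is missing or malformed."""


class UnsupportedScanLevelError(DiaqcError):
    """A spectrum declares an MS level other than 1 or 2."""


class AmbiguousChannelError(DiaqcError):
    """A modified sequence carries conflicting multiplexing-label tags."""


class DegenerateInputError(DiaqcError):
    """Input is structurally valid but carries no usable signal."""


class ConfigError(DiaqcError):
    """A configuration value is missing or out of range."""
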