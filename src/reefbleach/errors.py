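"""Exception hierarchy shared across the package."""


class ReefBleachError(Exception):
    """Base class for all package errors."""


class FormatError(ReefBleachError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(ReefBleachError):
    """Record-level content is invalid (bad category code, negative count...)."""


class UndefinedIndexError(ReefBleachError):
    """An index is requested for a stratum with no colonies to support it."""


class ParameterError(ReefBleachError):
    """A caller-supplied parameter is out of its valid range."""
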