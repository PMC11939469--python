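"""Exception hierarchy for ovifeed.

Every error raised by the package derives from :class:`OvifeedError` so callers
can catch pipeline failures with a single except clause.
"""


class OvifeedError(Exception):
    """Base class for all ovifeed errors."""


class FormatError(OvifeedError):
    """A file does not conform to its declared format, or a record violates an invariant."""


class DuplicateRecordError(FormatError):
    """Two records share a key that must be unique, e.g. (animal, day)."""


class TruncationError(FormatError):
    """A binary file is shorter or longer than its header implies."""


class UnsupportedModeError(FormatError):
    """A recognised format in a mode this reader does not support (e.g. individual-major .bed)."""


class ConfigurationError(OvifeedError):
    """A configuration value is out of range or internally inconsistent."""


class InsufficientDataError(OvifeedError):
    """Too few observations for the requested fit."""


class SingularFitError(OvifeedError):
    """Design matrix is rank deficient or numerically collinear."""


class EmptyPanelError(OvifeedError):
    """Quality control removed every SNP (or every individual)."""
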