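"""Exception hierarchy.

All marrowmap errors derive from :class:`MarrowMapError` so callers can
catch the package's failures with a single except clause; subclasses also
derive from the closest builtin (ValueError/IOError) so generic handling
keeps working.
"""


class MarrowMapError(Exception):
    """Base class for all marrowmap errors."""


class ValidationError(MarrowMapError, ValueError):
    """Input data violate a documented precondition (non-finite values, bad shapes)."""


class ConfigurationError(MarrowMapError, ValueError):
    """A panel, rule set, threshold or scaling configuration is inconsistent."""


class ChannelMismatchError(ConfigurationError):
    """A sample is missing a channel the panel requires, or channel orders disagree."""


class UnsupportedDialectError(MarrowMapError, IOError):
    """An FCS file declares a version/datatype/mode outside the supported subset."""


class CorruptFileError(MarrowMapError, IOError):
    """An FCS file's segments are truncated or internally inconsistent."""


class NumericalError(MarrowMapError, ArithmeticError):
    """A numerical operation cannot proceed (e.g. singular spillover matrix)."""
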