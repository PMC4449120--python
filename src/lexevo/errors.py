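"""Exception hierarchy shared across the toolkit."""


class LexevoError(Exception):
    """Base class for all lexevo errors."""


class FormatError(LexevoError):
    """A file could not be parsed (missing column, malformed block, ...)."""


class DataError(LexevoError):
    """Input data violates a precondition (empty table, no overlap, ...)."""


class GeometryError(LexevoError):
    """Site geometry is degenerate (collinear, duplicated coordinates)."""


class NumericError(LexevoError):
    """A numerical routine failed (non-finite value, bad denominator)."""


class ConfigError(LexevoError):
    """A configuration file or object is invalid."""
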