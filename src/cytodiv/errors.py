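"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3, NumericError -> 4.
"""


class CytodivError(Exception):
    """Base class for all package errors."""


class ConfigError(CytodivError):
    """Invalid or incomplete run configuration / gate definition."""


class DataError(CytodivError):
    """Problems with input data files."""


class FormatError(DataError):
    """Unsupported or malformed FCS file."""


class IntegrityError(DataError):
    """Declared metadata inconsistent with the data segment (e.g. $TOT)."""


class NumericError(CytodivError):
    """Degenerate numerical situation (zero IQR, all-zero sample, ...)."""
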