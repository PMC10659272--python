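"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (config -> 2, data -> 3, anything
else -> 4), so stages should raise the most specific class that applies.
"""


class BrainAgingError(Exception):
    """Base class for all package errors."""


class ConfigError(BrainAgingError):
    """Invalid configuration or parameters."""


class DataError(BrainAgingError):
    """Invalid, malformed, or degenerate input data."""


class ParseError(DataError):
    """A file failed to parse; message names the file and, where known, the line."""


class ValidationError(DataError):
    """A record violated an invariant (e.g. inverted interval coordinates)."""


class ContextUnassignableError(DataError):
    """A mutation's trinucleotide context contains a non-ACGT base."""
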