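"""Exception hierarchy used across the pipeline.

Every error raised on bad user input derives from :class:`TrendshiftError`
so callers (and the CLI) can map them onto exit codes: input problems → 2,
insufficient data → 3.
"""


class TrendshiftError(Exception):
    """Base class for all package errors."""


class ParseError(TrendshiftError):
    """A file could not be parsed; the message names the offending row."""


class ConflictError(TrendshiftError):
    """Duplicate keys where uniqueness is required (terms, term-weeks)."""


class InputError(TrendshiftError):
    """Invalid argument values (probabilities out of range, length mismatch...)."""


class RangeError(TrendshiftError):
    """A week falls outside the configured analysis window."""


class ConfigError(TrendshiftError):
    """Inconsistent configuration (e.g. window longer than the series)."""


class DegenerateInputError(TrendshiftError):
    """Inputs that make an estimator undefined (fewer than 2 distinct times...)."""


class InsufficientDataError(TrendshiftError):
    """Not enough observations/clusters/years to run the requested test."""
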