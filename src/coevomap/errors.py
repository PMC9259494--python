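"""Exception hierarchy shared across the pipeline.

All coevomap errors derive from :class:`CoevomapError` so callers (and the
CLI) can distinguish configuration problems from data problems.
"""


class CoevomapError(Exception):
    """Base class for all coevomap errors."""


class ConfigError(CoevomapError):
    """Invalid configuration: bad thresholds, unknown keys, missing paths."""


class ParseError(CoevomapError):
    """A file could not be parsed; the message names the offending line."""


class DataError(CoevomapError):
    """Well-formed input violating a domain invariant (range, length, sum)."""


class MappingError(CoevomapError):
    """A chain or family referenced in a mapping is absent from the data."""


class FeasibilityError(CoevomapError):
    """A synthetic-structure request that cannot satisfy its distance
    constraints."""


class EmptyInputError(CoevomapError):
    """An operation that requires a non-empty input received an empty one."""
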