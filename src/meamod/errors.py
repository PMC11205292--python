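"""Typed exceptions raised across the pipeline.

Every malformed input raises one of these; no stage ever returns a
partially constructed object.
"""


class MeamodError(Exception):
    """Base class for all package errors."""


class FormatError(MeamodError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(MeamodError):
    """An in-memory object violates a declared invariant."""


class ConfigurationError(MeamodError):
    """Required configuration (e.g. a sample rate) is missing or inconsistent."""


class DegenerateInputError(MeamodError):
    """Input too degenerate for the requested operation (e.g. < k distinct values)."""


class InsufficientDataError(MeamodError):
    """Not enough data to make a statistically meaningful decision."""


class UndefinedIndexError(MeamodError):
    """A cluster-validity index is undefined (e.g. coincident centroids)."""


class GenerationError(MeamodError):
    """The synthetic-data configuration is infeasible."""


class ConsistencyError(MeamodError):
    """Stage outputs that should describe the same recording disagree."""
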