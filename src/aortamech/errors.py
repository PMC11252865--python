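"""Exception hierarchy for aortamech."""


class AortamechError(Exception):
    """Base class for all aortamech errors."""


class InvalidSpecimenError(AortamechError):
    """Specimen geometry is non-physical (non-positive dimension, zero cross-section)."""


class MalformedRecordError(AortamechError):
    """A force-displacement record violates its invariants (decreasing d, negative F)."""


class DegenerateTransitionError(AortamechError):
    """Low- and high-stretch regression lines are parallel; no transition point exists."""


class GeometryError(AortamechError):
    """Ring / landmark geometry is degenerate (outer <= inner perimeter, zero-length ray)."""


class MalformedMarksError(AortamechError):
    """Pre-stretch mark positions violate their invariants (wrong count, non-increasing)."""


class NoTissueError(AortamechError):
    """The tissue mask is empty; area-normalised quantities are undefined."""


class ConfigurationError(AortamechError):
    """Invalid analysis configuration (e.g. singular stain matrix)."""


class GeneratorError(AortamechError):
    """A synthetic-data generator was asked for an infeasible scene or curve."""


class InsufficientDataError(AortamechError):
    """Too few samples for the requested statistic."""
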