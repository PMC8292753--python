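"""Exception hierarchy for the circalux pipeline.

Every stage raises a named subclass of :class:`CircaluxError` so callers
(and the CLI) can report which contract was violated without string matching.
"""


class CircaluxError(Exception):
    """Base class for all circalux errors."""


class FormatError(CircaluxError, ValueError):
    """A sensor file could not be parsed (names the offending line)."""


class OrderingError(CircaluxError, ValueError):
    """Timestamps in a sensor file are not strictly increasing."""


class EmptyInputError(CircaluxError, ValueError):
    """A sensor file or series contains no readings."""


class UnsupportedLatitudeError(CircaluxError, ValueError):
    """Solar events are undefined (polar day/night) at the requested latitude."""


class InsufficientDataError(CircaluxError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(CircaluxError, ValueError):
    """The statistic is undefined for this input (e.g. RSE with zero mean)."""


class ImputationFailureError(CircaluxError, ValueError):
    """A slot-column has no observed donor values anywhere."""


class DegenerateInputError(CircaluxError, ValueError):
    """An input has zero variance where variation is required."""


class CollinearityError(CircaluxError, ValueError):
    """The regression design matrix is rank deficient."""


class AlignmentError(CircaluxError, ValueError):
    """Two series expected on the same grid are misaligned."""


class MissingArtifactError(CircaluxError, FileNotFoundError):
    """A pipeline output required by a later stage is absent."""
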