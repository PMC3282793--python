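"""Exception hierarchy for barcodegap.

All package errors derive from :class:`BarcodegapError` so callers can catch
everything the pipeline may raise with a single except clause.
"""


class BarcodegapError(Exception):
    """Base class for all barcodegap errors."""


class AlignmentShapeError(BarcodegapError):
    """A record's length disagrees with the alignment length (ragged input)."""


class MetadataError(BarcodegapError):
    """A FASTA record has no metadata row, or a metadata row is malformed."""


class DuplicateSampleError(BarcodegapError):
    """The same sample_id occurs more than once in one locus or metadata table."""


class InsufficientOverlapError(BarcodegapError):
    """Fewer than two samples are shared across the loci being concatenated."""


class InsufficientDataError(BarcodegapError):
    """An operation needs more members/observations than were supplied."""


class UndefinedDistanceError(BarcodegapError):
    """A sequence pair shares zero comparable sites."""


class SaturationError(BarcodegapError):
    """The K2P log argument is non-positive (substitution saturation).

    Carries the transition proportion ``P`` and transversion proportion ``Q``
    of the offending pair.
    """

    def __init__(self, message: str, P: float, Q: float):
        super().__init__(message)
        self.P = P
        self.Q = Q


class DegenerateTestError(BarcodegapError):
    """A rank test has no non-zero differences to rank."""


class ValidationError(BarcodegapError):
    """A configuration object violates its invariants."""


class BoundsError(BarcodegapError):
    """A position/index falls outside the structure it addresses."""
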