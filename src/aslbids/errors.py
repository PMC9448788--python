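"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`AslBidsError` so callers can catch a
single base class at API boundaries (the CLI maps them to exit code 2).
"""


class AslBidsError(Exception):
    """Base class for all toolkit errors."""


# --- on-disk layout / parsing -------------------------------------------------

class MissingFileError(AslBidsError):
    """A file required by the BIDS layout does not exist."""


class AmbiguousLayoutError(AslBidsError):
    """Multiple candidate files exist where exactly one is expected."""


class MalformedJsonError(AslBidsError):
    """A JSON sidecar could not be parsed."""


class MalformedTsvError(AslBidsError):
    """An ``_aslcontext.tsv`` file violates the single-column contract."""


class TypeMismatchError(AslBidsError):
    """A sidecar value does not conform to the registered value kind."""

    def __init__(self, field: str, message: str):
        super().__init__(message)
        self.field = field


class IoFailureError(AslBidsError):
    """Writing the dataset tree failed."""


# --- conversion ---------------------------------------------------------------

class ZeroSlopeError(AslBidsError):
    """Scale slope of zero is not invertible."""


class NotAPermutationError(AslBidsError):
    """The export-order map is not a bijection of 0..n-1."""


class LengthMismatchError(AslBidsError):
    """Series, context, and order map lengths disagree."""


# --- synthesizer --------------------------------------------------------------

class UnknownExampleError(AslBidsError):
    """Requested example plan name is not one of asl001..asl005."""


class InvalidPlanError(AslBidsError):
    """An acquisition plan violates its own invariants."""


class UnknownViolationError(AslBidsError):
    """Requested mutation id is not in the published catalogue."""


# --- quantification -----------------------------------------------------------

class UnpairableContextError(AslBidsError):
    """Control/label rows cannot be paired and no deltam rows exist."""


class M0UnavailableError(AslBidsError):
    """No M0 information usable as the calibration denominator."""


class MissingSliceTimingError(AslBidsError):
    """2D acquisition without SliceTiming; effective PLD undefined."""


class UnsupportedSchemeError(AslBidsError):
    """Labeling/readout combination outside the single-PLD model."""


class UnknownFieldStrengthError(AslBidsError):
    """No default relaxation constants tabulated for this field strength."""
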