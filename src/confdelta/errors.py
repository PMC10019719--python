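"""Exception hierarchy.

Every error raised on bad scientific input derives from :class:`ConfDeltaError`
so callers can distinguish data problems from programming errors.
"""


class ConfDeltaError(ValueError):
    """Base class for all domain errors."""


class MutationParseError(ConfDeltaError):
    """A mutation code does not match ``<wt><position><mut>``."""


class SynonymousMutationError(MutationParseError):
    """Wild-type and mutant residues are identical."""


class ReferenceMismatchError(ConfDeltaError):
    """Sequence does not carry the stated wild-type residue at the position."""


class MissingSequenceError(ConfDeltaError):
    """A mutation references a protein with no sequence supplied."""


class MalformedModelError(ConfDeltaError):
    """A coordinate file violates the single-chain / CA-per-residue contract."""


class EmptyProfileError(ConfDeltaError):
    """A score-array file contains no residues."""


class InconsistentModelsError(ConfDeltaError):
    """Profiles being compared or pooled have different lengths."""


class ScoreRangeError(ConfDeltaError):
    """A per-residue confidence score falls outside [0, 100]."""


class LookupError_(ConfDeltaError):
    """An amino acid is missing from a property table."""


class UndefinedCorrelationError(ConfDeltaError):
    """Correlation requested for a constant vector."""


class UndefinedFractionError(ConfDeltaError):
    """Sign enrichment requested with no destabilizing mutations."""


class EmptyInputError(ConfDeltaError):
    """An input table or group is empty where data are required."""
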