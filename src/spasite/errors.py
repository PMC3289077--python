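"""Exception hierarchy for spasite.

All package-raised errors derive from :class:`SpasiteError` so callers can
catch one base class at the CLI boundary.
"""


class SpasiteError(Exception):
    """Base class for all spasite errors."""


class StructureParseError(SpasiteError):
    """A structure file could not be parsed."""


class EmptyStructureError(SpasiteError):
    """A structure contains no usable protein residues."""


class MissingAtomsError(SpasiteError):
    """A residue lacks the atoms required for the requested computation."""


class AnnotationParseError(SpasiteError):
    """A DSSP (or annotation TSV) file could not be parsed."""


class EmptyAnnotationError(SpasiteError):
    """An annotation source yielded zero residue records."""


class UnknownElementError(SpasiteError):
    """An atom's element has no van der Waals radius in the table."""


class ProfileParseError(SpasiteError):
    """A PSSM or profile TSV file could not be parsed."""


class SequenceMismatchError(SpasiteError):
    """Profile residue letters disagree with the structure's sequence."""


class InvalidSequenceError(SpasiteError):
    """A sequence contains a letter outside the amino-acid alphabet."""


class InvalidWindowError(SpasiteError):
    """A window width violates an encoding's precondition (e.g. even w)."""


class ShortChainError(SpasiteError):
    """A chain has fewer protein residues than the requested window."""


class MissingProfileError(SpasiteError):
    """A residue index has no profile row."""


class MissingAnnotationError(SpasiteError):
    """A residue index has no annotation record."""


class EmptyTableError(SpasiteError):
    """Featurization produced zero usable rows."""


class DegenerateTrainingError(SpasiteError):
    """Training data contains a single class."""


class DegenerateModelError(SpasiteError):
    """A model without support vectors was asked for a decision value."""


class EmptyCountsError(SpasiteError):
    """A confusion matrix with N=0 cannot yield metrics."""


class SplitError(SpasiteError):
    """A cross-validation split is infeasible for the given data."""


class FixtureSpecError(SpasiteError):
    """A synthetic fixture specification is invalid."""
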