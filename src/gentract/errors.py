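"""Exception hierarchy.

Every hard failure raises a named subclass of :class:`GentractError` so
callers (and the CLI) can distinguish user errors from internal defects.
"""


class GentractError(Exception):
    """Base class for all errors raised by gentract."""


class EmptyFastaError(GentractError):
    """A FASTA file contained no records."""


class CutSiteOutOfBoundsError(GentractError):
    """The predicted cut site lies outside the reference sequence."""


class ReferenceMismatchError(GentractError):
    """The alignment header does not match the reference locus."""


class MalformedCigarError(GentractError):
    """CIGAR operations are inconsistent with the read sequence."""


class DonorAlignmentError(GentractError):
    """Donor/reference alignment does not fit the arms-plus-insertion model."""


class AmbiguousInsertionError(DonorAlignmentError):
    """More than one candidate donor insertion placement was found."""


class SnpFreeDonorError(GentractError):
    """Tract analysis requested for a donor with no cataloged SNPs."""


class EmptyInputError(GentractError):
    """An operation that requires at least one read received none."""


class LocusMismatchError(GentractError):
    """Two tables/samples were built against different loci."""
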