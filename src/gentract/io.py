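"""Reference and alignment input.

All coordinates inside the package are 0-based, half-open. The single
conversion from SAM's 1-based POS happens here, at load time, and nowhere
else. Amplicon reads are expected to be aligned to a single reference
sequence (the amplicon) by an external long-read aligner; this module only
consumes the resulting SAM/BAM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .errors import (
    CutSiteOutOfBoundsError,
    EmptyFastaError,
    MalformedCigarError,
    ReferenceMismatchError,
)

logger = logging.getLogger("gentract")

#: SAM operations that consume query sequence / reference sequence.
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")
_CIGAR_ALPHABET = "MIDNSHP=X"

Cigar = tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class ReferenceLocus:
    """The amplicon reference plus the predicted nuclease cut position.

    The *target window* is the closed interval of reference positions within
    ``window_halfwidth`` bp of the cut site; indels anchored or overlapping
    there are counted as cut-site variants.
    """

    name: str
    sequence: str
    cut_site: int
    window_halfwidth: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise EmptyFastaError(f"reference {self.name!r} has empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"reference contains non-ACGTN symbols: {sorted(bad)}")
        if not 0 <= self.cut_site < len(self.sequence):
            raise CutSiteOutOfBoundsError(
                f"cut_site {self.cut_site} outside [0, {len(self.sequence)}) "
                f"for reference {self.name!r}"
            )
        if self.window_halfwidth < 0:
            raise ValueError("window_halfwidth must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def window(self) -> tuple[int, int]:
        """Closed interval [lo, hi] of the target window, clipped to bounds."""
        lo = max(0, self.cut_site - self.window_halfwidth)
        hi = min(len(self.sequence) - 1, self.cut_site + self.window_halfwidth)
        return lo, hi


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read with its CIGAR, in package coordinates (0-based)."""

    read_id: str
    sample_id: str
    ref_start: int
    cigar: Cigar
    query_sequence: str
    is_mapped: bool = True
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.is_mapped and self.ref_start < 0:
            raise ValueError("mapped read with negative ref_start")
        qlen = 0
        for op, ln in self.cigar:
            if op not in _CIGAR_ALPHABET:
                raise MalformedCigarError(f"unknown CIGAR op {op!r} in {self.read_id}")
            if ln < 1:
                raise MalformedCigarError(f"non-positive CIGAR length in {self.read_id}")
            if op in QUERY_OPS:
                qlen += ln
        if self.query_sequence and qlen != len(self.query_sequence):
            raise MalformedCigarError(
                f"{self.read_id}: CIGAR consumes {qlen} query bases but "
                f"sequence has {len(self.query_sequence)}"
            )

    @property
    def ref_end(self) -> int:
        """One past the last reference position covered by the alignment."""
        return self.ref_start + sum(ln for op, ln in self.cigar if op in REF_OPS)

    @property
    def cigar_string(self) -> str:
        return "".join(f"{ln}{op}" for op, ln in self.cigar)


@dataclass
class AlignmentFilterStats:
    """Per-file accounting so every denominator is auditable."""

    total_records: int = 0
    yielded: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    low_mapq: int = 0
    other_reference: int = 0

    @property
    def filtered(self) -> int:
        return self.total_records - self.yielded

    def as_dict(self) -> dict[str, int]:
        return {
            "total_records": self.total_records,
            "yielded": self.yielded,
            "unmapped": self.unmapped,
            "secondary": self.secondary,
            "supplementary": self.supplementary,
            "low_mapq": self.low_mapq,
            "other_reference": self.other_reference,
        }


def load_reference(
    path: str | Path,
    cut_site: int,
    *,
    window_halfwidth: int = 4,
    name: str | None = None,
) -> ReferenceLocus:
    """Load the first FASTA record as the amplicon reference.

    Raises ``FileNotFoundError`` for a missing file, ``EmptyFastaError`` for a
    FASTA without records and ``CutSiteOutOfBoundsError`` when ``cut_site``
    does not fall inside the sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    return ReferenceLocus(
        name=name or rec.id,
        sequence=str(rec.seq),
        cut_site=cut_site,
        window_halfwidth=window_halfwidth,
    )


def load_fasta_sequence(path: str | Path) -> str:
    """First FASTA record's sequence, uppercased (used for donors)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(f"{path} contains {len(records)} records; using the first", stacklevel=2)
    return str(records[0].seq).upper()


def _cigartuples_to_cigar(cigartuples: Iterable[tuple[int, int]]) -> Cigar:
    return tuple((_CIGAR_ALPHABET[op], ln) for op, ln in cigartuples)


def iter_alignments(
    path: str | Path,
    locus: ReferenceLocus,
    *,
    min_mapq: int = 1,
    sample_id: str | None = None,
    stats: AlignmentFilterStats | None = None,
) -> Iterator[AlignedRead]:
    """Stream mapped, primary, non-supplementary reads from a SAM/BAM file.

    The file header must contain the locus' reference name with a matching
    length; a mismatch is a hard :class:`ReferenceMismatchError` (silently
    analyzing reads aligned to a different amplicon would corrupt every
    downstream frequency). SAM 1-based POS becomes 0-based ``ref_start``.

    ``sample_id`` resolution order: explicit argument, read-group ``SM`` tag,
    file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if stats is None:
        stats = AlignmentFilterStats()

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        if locus.name not in af.references:
            raise ReferenceMismatchError(
                f"{path}: header references {list(af.references)!r} do not "
                f"include locus {locus.name!r}"
            )
        header_len = af.get_reference_length(locus.name)
        if header_len != len(locus.sequence):
            raise ReferenceMismatchError(
                f"{path}: header length {header_len} for {locus.name!r} != "
                f"reference length {len(locus.sequence)}"
            )
        rg_sm = {
            rg.get("ID"): rg.get("SM", rg.get("ID"))
            for rg in af.header.to_dict().get("RG", [])
        }
        default_sample = sample_id or (
            next(iter(rg_sm.values())) if len(rg_sm) == 1 else path.stem
        )

        for rec in af:
            stats.total_records += 1
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            if rec.is_secondary:
                stats.secondary += 1
                continue
            if rec.is_supplementary:
                stats.supplementary += 1
                continue
            if rec.reference_name != locus.name:
                stats.other_reference += 1
                continue
            if rec.mapping_quality < min_mapq:
                stats.low_mapq += 1
                continue
            sid = default_sample
            if sample_id is None and rec.has_tag("RG"):
                sid = rg_sm.get(rec.get_tag("RG"), default_sample)
            stats.yielded += 1
            yield AlignedRead(
                read_id=rec.query_name,
                sample_id=sid,
                ref_start=rec.reference_start,
                cigar=_cigartuples_to_cigar(rec.cigartuples or ()),
                query_sequence=(rec.query_sequence or "").upper(),
                is_mapped=True,
                mapq=rec.mapping_quality,
            )


def load_alignments(
    path: str | Path,
    locus: ReferenceLocus,
    *,
    min_mapq: int = 1,
    sample_id: str | None = None,
) -> tuple[list[AlignedRead], AlignmentFilterStats]:
    """Materialize :func:`iter_alignments` and return reads with filter stats."""
    stats = AlignmentFilterStats()
    reads = list(
        iter_alignments(path, locus, min_mapq=min_mapq, sample_id=sample_id, stats=stats)
    )
    logger.info(
        "%s: %d records, %d analyzed (%d unmapped, %d secondary, %d supplementary, "
        "%d low-mapq, %d other-reference)",
        path,
        stats.total_records,
        stats.yielded,
        stats.unmapped,
        stats.secondary,
        stats.supplementary,
        stats.low_mapq,
        stats.other_reference,
    )
    return reads, stats


def write_fasta(path: str | Path, name: str, sequence: str, width: int = 60) -> None:
    """Write a single-record FASTA with fixed line wrapping (deterministic)."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
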