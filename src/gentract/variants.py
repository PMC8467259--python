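"""Cut-site indel extraction and background-subtracted mutagenesis.

Targeted mutagenesis (imprecise repair) is quantified from insertions and
deletions whose CIGAR placement intersects the target window around the
predicted cut site. Because long-read base error also produces indels, a
matched no-nuclease control sample is tabulated with the same rules and
subtracted variant-by-variant; only post-subtraction frequencies above a
threshold (default 0.5%) contribute to the adjusted mutagenesis frequency.

Variant identity is the key ``(type, ref_pos, length)``; the inserted
sequence is deliberately not part of the key, since per-base error would
fragment sequence-exact keys for the same underlying event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import EmptyInputError, LocusMismatchError
from .io import AlignedRead, ReferenceLocus

INSERTION = "insertion"
DELETION = "deletion"

VariantKey = tuple[str, int, int]  # (vtype, ref_pos, length)


@dataclass(frozen=True)
class VariantRecord:
    """One indel observation on one read.

    For insertions ``ref_pos`` is the reference position before which the
    bases are inserted (the anchor); for deletions it is the first deleted
    reference position.
    """

    vtype: str
    ref_pos: int
    length: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.vtype not in (INSERTION, DELETION):
            raise ValueError(f"bad variant type {self.vtype!r}")
        if self.length < 1:
            raise ValueError("variant length must be >= 1")
        if self.vtype == INSERTION and len(self.sequence) != self.length:
            raise ValueError("insertion length != sequence length")

    @property
    def key(self) -> VariantKey:
        return (self.vtype, self.ref_pos, self.length)


def extract_window_variants(read: AlignedRead, locus: ReferenceLocus) -> list[VariantRecord]:
    """Indels from the read's CIGAR that intersect the target window.

    An insertion intersects when its anchor lies in the closed window; a
    deletion when its reference interval overlaps the window. Variants are
    returned in read (left-to-right reference) order.
    """
    lo, hi = locus.window
    out: list[VariantRecord] = []
    rpos = read.ref_start
    qpos = 0
    for op, ln in read.cigar:
        if op in ("M", "=", "X"):
            rpos += ln
            qpos += ln
        elif op == "I":
            if lo <= rpos <= hi:
                out.append(
                    VariantRecord(INSERTION, rpos, ln, read.query_sequence[qpos : qpos + ln])
                )
            qpos += ln
        elif op in ("D", "N"):
            if rpos <= hi and rpos + ln - 1 >= lo:
                out.append(VariantRecord(DELETION, rpos, ln))
            rpos += ln
        elif op == "S":
            qpos += ln
        # H and P consume nothing relevant
    return out


def merge_window_insertions(variants: Iterable[VariantRecord]) -> Optional[str]:
    """Concatenate all window insertions of one read, in read order.

    Long-read error fragments long insertions into several CIGAR ``I`` runs;
    the concatenation is the candidate modification handed to GT matching.
    Returns ``None`` when the read has no window insertion.
    """
    parts = [v.sequence for v in variants if v.vtype == INSERTION]
    if not parts:
        return None
    return "".join(parts)


@dataclass
class VariantTable:
    """Per-sample window-variant counts and frequencies (percent)."""

    sample_id: str
    locus_name: str
    total_reads: int
    counts: dict[VariantKey, int]
    reads_with_variant: int

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise EmptyInputError(f"sample {self.sample_id!r}: no reads tabulated")

    @property
    def frequencies(self) -> dict[VariantKey, float]:
        return {k: 100.0 * c / self.total_reads for k, c in self.counts.items()}

    @property
    def reads_with_variant_pct(self) -> float:
        return 100.0 * self.reads_with_variant / self.total_reads


@dataclass
class MutagenesisResult:
    """Adjusted targeted-mutagenesis frequency after control subtraction."""

    sample_id: str
    total_reads: int
    raw_variant_read_pct: float
    adjusted_frequency_pct: float
    contributing_variants: list[tuple[VariantKey, float]]
    control_sample_id: Optional[str] = None
    control_subtracted: bool = True


def tabulate_variants(
    reads: Iterable[AlignedRead],
    locus: ReferenceLocus,
    *,
    sample_id: str | None = None,
    exclude_read_ids: set[str] | None = None,
) -> VariantTable:
    """Build the per-sample variant table.

    Each read contributes at most one count per distinct variant key, and
    counts once toward ``reads_with_variant`` regardless of how many window
    variants it carries. ``exclude_read_ids`` removes reads (e.g. GT-positive
    reads, whose donor insertion is not mutagenesis) from both numerator and
    denominator.
    """
    counts: dict[VariantKey, int] = {}
    total = 0
    with_variant = 0
    sid = sample_id
    for read in reads:
        if exclude_read_ids and read.read_id in exclude_read_ids:
            continue
        if sid is None:
            sid = read.sample_id
        total += 1
        keys = {v.key for v in extract_window_variants(read, locus)}
        if keys:
            with_variant += 1
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
    if total == 0:
        raise EmptyInputError("no reads to tabulate")
    return VariantTable(
        sample_id=sid or "sample",
        locus_name=locus.name,
        total_reads=total,
        counts=counts,
        reads_with_variant=with_variant,
    )


def subtract_background(
    treated: VariantTable,
    control: Optional[VariantTable],
    threshold_pct: float = 0.5,
) -> MutagenesisResult:
    """Variant-specific control subtraction with frequency thresholding.

    For every key observed in the treated sample the control frequency (0 if
    absent) is subtracted; keys whose post-subtraction frequency exceeds
    ``threshold_pct`` sum to the adjusted targeted-mutagenesis frequency.
    With no control the subtraction degenerates to thresholding the raw
    frequencies (flagged in the result and warned about).
    """
    if control is not None and control.locus_name != treated.locus_name:
        raise LocusMismatchError(
            f"treated locus {treated.locus_name!r} != control locus {control.locus_name!r}"
        )
    if control is None:
        warnings.warn(
            f"sample {treated.sample_id!r}: no control sample; adjusted frequency "
            "is raw thresholded frequency and includes platform error",
            stacklevel=2,
        )
    control_freq = control.frequencies if control is not None else {}
    contributing: list[tuple[VariantKey, float]] = []
    for key, freq in sorted(treated.frequencies.items()):
        diff = freq - control_freq.get(key, 0.0)
        if diff > threshold_pct:
            contributing.append((key, diff))
    adjusted = sum(d for _, d in contributing)
    return MutagenesisResult(
        sample_id=treated.sample_id,
        total_reads=treated.total_reads,
        raw_variant_read_pct=treated.reads_with_variant_pct,
        adjusted_frequency_pct=adjusted,
        contributing_variants=contributing,
        control_sample_id=control.sample_id if control is not None else None,
        control_subtracted=control is not None,
    )


def variant_report_frame(
    treated: VariantTable,
    control: Optional[VariantTable],
    result: MutagenesisResult,
) -> pd.DataFrame:
    """One row per variant key: counts, frequencies and subtraction outcome."""
    control_freq = control.frequencies if control is not None else {}
    contributing = dict(result.contributing_variants)
    rows = []
    for key in sorted(treated.counts):
        vtype, ref_pos, length = key
        freq = treated.frequencies[key]
        cfreq = control_freq.get(key, 0.0)
        rows.append(
            {
                "sample_id": treated.sample_id,
                "vtype": vtype,
                "ref_pos": ref_pos,
                "length": length,
                "count": treated.counts[key],
                "frequency_pct": freq,
                "control_frequency_pct": cfreq,
                "subtracted_pct": freq - cfreq,
                "contributes": "yes" if key in contributing else "no",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "vtype",
            "ref_pos",
            "length",
            "count",
            "frequency_pct",
            "control_frequency_pct",
            "subtracted_pct",
            "contributes",
        ],
    )
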