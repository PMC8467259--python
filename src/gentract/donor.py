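"""Donor decomposition: homology arms, expected insertion, SNP catalog.

A gene-targeting donor is modeled as ``LHA + insertion + RHA`` relative to
the reference amplicon: two homology arms copied from the reference (possibly
carrying engineered or natural SNPs) flanking a single insertion placed at
the predicted cut site. The decomposition is recovered from a global pairwise
alignment of donor against reference; the insertion is left-aligned (standard
variant normalization) so its coordinate is deterministic, and every arm
mismatch becomes a cataloged :class:`DonorSNP`.

SNP distances are signed bp from the insertion point: the first reference
base left of the insertion is −1 and the first base right of it is +1, so a
donor with SNPs every 30 bp yields distances ±30, ±60, ... and the catalog
mirrors exactly under reverse complement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from .errors import AmbiguousInsertionError, DonorAlignmentError
from .io import ReferenceLocus

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DonorSNP:
    """One donor/reference mismatch inside a homology arm."""

    ref_pos: int  # 0-based reference coordinate
    ref_base: str
    donor_base: str
    arm: str  # "left" | "right"
    distance: int  # signed bp from the insertion point; negative = left arm

    def __post_init__(self) -> None:
        if self.ref_base == self.donor_base:
            raise ValueError("DonorSNP with identical bases")
        if self.arm not in ("left", "right"):
            raise ValueError(f"bad arm {self.arm!r}")
        if (self.distance < 0) != (self.arm == "left") or self.distance == 0:
            raise ValueError("arm inconsistent with sign of distance")


@dataclass(frozen=True)
class DonorSpec:
    """Derived donor model: insertion plus ordered SNP catalog.

    ``left_arm_span`` / ``right_arm_span`` are half-open reference intervals
    of donor/reference homology (``None`` for a single-arm donor). ``snps``
    are sorted by reference position.
    """

    donor_sequence: str
    insertion_sequence: str
    insertion_position: int  # bases inserted before this reference position
    left_arm_span: tuple[int, int] | None
    right_arm_span: tuple[int, int] | None
    snps: tuple[DonorSNP, ...] = ()

    def __post_init__(self) -> None:
        if len(self.insertion_sequence) < 1:
            raise ValueError("insertion_sequence must be non-empty")
        if list(self.snps) != sorted(self.snps, key=lambda s: s.ref_pos):
            raise ValueError("snps must be sorted by ref_pos")

    @property
    def left_snps(self) -> tuple[DonorSNP, ...]:
        """Left-arm SNPs ordered outward from the insertion (innermost first)."""
        return tuple(
            sorted((s for s in self.snps if s.arm == "left"), key=lambda s: -s.distance)
        )

    @property
    def right_snps(self) -> tuple[DonorSNP, ...]:
        """Right-arm SNPs ordered outward from the insertion (innermost first)."""
        return tuple(
            sorted((s for s in self.snps if s.arm == "right"), key=lambda s: s.distance)
        )

    def reconstruct(self, locus: ReferenceLocus) -> str:
        """Splice insertion + SNPs into the reference homologous region.

        Used as an internal consistency check: the result must equal the
        donor's homologous region exactly.
        """
        l0 = self.left_arm_span[0] if self.left_arm_span else self.insertion_position
        r1 = self.right_arm_span[1] if self.right_arm_span else self.insertion_position
        region = list(locus.sequence[l0:r1])
        for snp in self.snps:
            if region[snp.ref_pos - l0] != snp.ref_base:
                raise DonorAlignmentError(
                    f"SNP at {snp.ref_pos} disagrees with reference base"
                )
            region[snp.ref_pos - l0] = snp.donor_base
        cut = self.insertion_position - l0
        return "".join(region[:cut]) + self.insertion_sequence + "".join(region[cut:])

    def to_json_dict(self) -> dict:
        return {
            "insertion_sequence": self.insertion_sequence,
            "insertion_position": self.insertion_position,
            "insertion_length": len(self.insertion_sequence),
            "left_arm_span": list(self.left_arm_span) if self.left_arm_span else None,
            "right_arm_span": list(self.right_arm_span) if self.right_arm_span else None,
            "n_snps": len(self.snps),
            "snps": [
                {
                    "ref_pos": s.ref_pos,
                    "ref_base": s.ref_base,
                    "donor_base": s.donor_base,
                    "arm": s.arm,
                    "distance": s.distance,
                }
                for s in self.snps
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n")


def snp_distance(ref_pos: int, insertion_position: int) -> int:
    """Signed bp from the insertion point (−1/+1 are the flanking bases)."""
    if ref_pos < insertion_position:
        return ref_pos - insertion_position
    return ref_pos - insertion_position + 1


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float,
                  local: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if local else "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if not local:
        # The reference amplicon may extend beyond the donor homology: its
        # overhangs (end gaps in the donor/query) are free.
        aligner.end_deletion_score = 0.0
    return aligner


def _walk_alignment(alignment, ref: str, donor: str):
    """Return (insertions, mismatches, aligned ref span, aligned donor span).

    insertions: list of (ref_pos, donor_segment); mismatches: list of
    (ref_pos, ref_base, donor_base). A donor-side deletion (reference bases
    absent from the donor inside the aligned region) is rejected: donors
    encoding deletions are out of scope.
    """
    tblocks, qblocks = alignment.aligned
    if len(tblocks) == 0:
        raise DonorAlignmentError("donor does not align to the reference")
    insertions: list[tuple[int, str]] = []
    mismatches: list[tuple[int, str, str]] = []
    for i in range(len(tblocks)):
        t0, t1 = int(tblocks[i][0]), int(tblocks[i][1])
        q0, q1 = int(qblocks[i][0]), int(qblocks[i][1])
        for t, q in zip(range(t0, t1), range(q0, q1)):
            if ref[t] != donor[q]:
                mismatches.append((t, ref[t], donor[q]))
        if i + 1 < len(tblocks):
            nt0 = int(tblocks[i + 1][0])
            nq0 = int(qblocks[i + 1][0])
            t_gap = nt0 - t1
            q_gap = nq0 - q1
            if t_gap > 0 and q_gap > 0:
                raise DonorAlignmentError(
                    "donor/reference alignment contains adjacent opposing gaps"
                )
            if q_gap > 0:  # donor-only bases: an insertion relative to reference
                insertions.append((t1, donor[q1:nq0]))
            elif t_gap > 0:  # reference-only bases: donor encodes a deletion
                raise DonorAlignmentError(
                    f"donor is missing {t_gap} reference bases at ref pos {t1}; "
                    "deletion-encoding donors are not supported"
                )
    ref_span = (int(tblocks[0][0]), int(tblocks[-1][1]))
    donor_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
    return insertions, mismatches, ref_span, donor_span


def _left_align_insertion(
    ref: str, pos: int, seq: str, mismatch_positions: set[int]
) -> tuple[int, str]:
    """Shift an insertion left while representations are equivalent.

    A shift across a reference position is valid only when that position is a
    match column (not a SNP) and the insertion's last base equals the
    reference base being crossed — the standard left normalization of
    insertions, restricted so the SNP catalog is preserved.
    """
    while pos > 0 and seq[-1] == ref[pos - 1] and (pos - 1) not in mismatch_positions:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def enumerate_equivalent_placements(ref: str, pos: int, seq: str) -> list[tuple[int, str]]:
    """All (position, sequence) placements of an insertion with identical
    resulting sequence. Brute-force helper used by tests as an oracle for the
    left-alignment rule."""
    placements = {(pos, seq)}
    p, s = pos, seq
    while p > 0 and s[-1] == ref[p - 1]:
        s = ref[p - 1] + s[:-1]
        p -= 1
        placements.add((p, s))
    p, s = pos, seq
    while p < len(ref) and s[0] == ref[p]:
        s = s[1:] + ref[p]
        p += 1
        placements.add((p, s))
    return sorted(placements)


def _decompose(
    aligner: Align.PairwiseAligner, ref: str, donor: str, terminal_as_insertion: bool
):
    """One alignment-based decomposition attempt.

    Returns ``(insertions, mismatches, ref_span)``. With
    ``terminal_as_insertion`` (local mode) unaligned terminal donor segments
    become insertion candidates, after peeling mismatch-dense arm edges back
    into the insertion: the local alignment may absorb insertion-edge bases
    that match the reference by chance, so the arm boundary abutting the
    insertion must start with ``guard`` clean match columns.
    """
    alignment = aligner.align(ref, donor)[0]
    insertions, mismatches, ref_span, donor_span = _walk_alignment(alignment, ref, donor)
    q0, q1 = donor_span
    t0, t1 = ref_span
    if not terminal_as_insertion:
        if donor_span != (0, len(donor)):
            raise DonorAlignmentError("global alignment left donor overhangs")
        return insertions, mismatches, ref_span
    guard = 10
    mm_pos = {p for p, _, _ in mismatches}
    if q0 > 0:
        while t0 < t1 and mm_pos & set(range(t0, min(t0 + guard, t1))):
            mm_pos.discard(t0)
            mismatches = [m for m in mismatches if m[0] != t0]
            t0 += 1
            q0 += 1
        insertions.insert(0, (t0, donor[:q0]))
    if q1 < len(donor):
        while t1 > t0 and mm_pos & set(range(max(t0, t1 - guard), t1)):
            mm_pos.discard(t1 - 1)
            mismatches = [m for m in mismatches if m[0] != t1 - 1]
            t1 -= 1
            q1 -= 1
        insertions.append((t1, donor[q1:]))
    return insertions, mismatches, (t0, t1)


def build_donor_spec(
    donor: str,
    locus: ReferenceLocus,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> DonorSpec:
    """Derive the :class:`DonorSpec` by aligning donor to reference.

    The donor must carry exactly one contiguous insertion relative to the
    reference (the targeted modification). Its placement is left-aligned; a
    placement that is still ambiguous raises
    :class:`AmbiguousInsertionError`. Arm mismatches become the ordered SNP
    catalog. A warning is emitted if the recovered insertion position is not
    the locus' predicted cut site.
    """
    donor = donor.upper()
    ref = locus.sequence
    if not donor:
        raise DonorAlignmentError("empty donor sequence")

    # Two decomposition hypotheses are scored and the more parsimonious one
    # (fewer arm mismatches, then fewer insertion segments) wins:
    #   * global (free reference end gaps) — the natural fit for a
    #     two-arm LHA + insertion + RHA donor;
    #   * local arm alignment with the unaligned terminal donor segment as
    #     the insertion — required for single-arm donors, where the global
    #     DP cannot leave a donor and a reference overhang at the same end
    #     and instead smears the insertion onto the reference.
    candidates = []
    for local in (False, True):
        aligner = _make_aligner(match, mismatch, gap_open, gap_extend, local=local)
        try:
            decomposed = _decompose(aligner, ref, donor, terminal_as_insertion=local)
        except DonorAlignmentError:
            continue
        insertions_c, mismatches_c, ref_span_c = decomposed
        if not insertions_c:
            continue
        cost = (len(insertions_c), len(mismatches_c), local)
        candidates.append((cost, insertions_c, mismatches_c, ref_span_c))
    if not candidates:
        raise DonorAlignmentError(
            "no donor-only insertion found; donor may be identical to the reference"
        )
    _, insertions, mismatches, ref_span = min(candidates, key=lambda c: c[0])
    if len(insertions) > 1:
        detail = ", ".join(f"{len(s)} bp at ref {p}" for p, s in insertions)
        raise AmbiguousInsertionError(
            f"expected a single contiguous donor insertion, found {len(insertions)}: {detail}"
        )

    ins_pos, ins_seq = insertions[0]
    mismatch_positions = {p for p, _, _ in mismatches}
    ins_pos, ins_seq = _left_align_insertion(ref, ins_pos, ins_seq, mismatch_positions)

    if ins_pos != locus.cut_site:
        warnings.warn(
            f"donor insertion recovered at reference position {ins_pos}, "
            f"not the predicted cut site {locus.cut_site}",
            stacklevel=2,
        )

    snps = tuple(
        DonorSNP(
            ref_pos=p,
            ref_base=rb,
            donor_base=db,
            arm="left" if p < ins_pos else "right",
            distance=snp_distance(p, ins_pos),
        )
        for p, rb, db in sorted(mismatches)
    )

    l0, r1 = ref_span
    left_span = (l0, ins_pos) if l0 < ins_pos else None
    right_span = (ins_pos, r1) if r1 > ins_pos else None

    spec = DonorSpec(
        donor_sequence=donor,
        insertion_sequence=ins_seq,
        insertion_position=ins_pos,
        left_arm_span=left_span,
        right_arm_span=right_span,
        snps=snps,
    )
    if spec.reconstruct(locus) != donor:
        raise DonorAlignmentError(
            "internal consistency check failed: insertion + SNP catalog does "
            "not reproduce the donor sequence"
        )
    return spec


def snps_inside_window(spec: DonorSpec, locus: ReferenceLocus) -> list[DonorSNP]:
    """SNPs whose |distance| falls within the indel target window."""
    return [s for s in spec.snps if abs(s.distance) <= locus.window_halfwidth]
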