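"""Conversion-tract phasing and smoothing for GT-positive reads.

Long reads preserve phase: each GT read reports, at every cataloged donor
SNP, whether the donor base was incorporated (DONOR) or the locus retained
its own base (WT). Per-base error corrupts individual SNP calls, so two
smoothing rules are applied per homology arm, scanning outward from the
insertion:

1. *Truncation* — any SNP external to the first run of ``run_length``
   (default 3) consecutive WT calls is forced WT. Isolated error-driven
   DONOR calls far from the insertion cannot masquerade as tract ends.
2. *Fill-in* — WT calls inside the putative tract (i.e. inward of the
   outermost surviving DONOR call) are set DONOR, rescuing interior SNPs
   lost to error.

After smoothing every arm's DONOR set is a contiguous prefix starting at the
insertion, and the tract extent is the |distance| of the outermost DONOR
SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .donor import DonorSNP, DonorSpec
from .errors import EmptyInputError, SnpFreeDonorError
from .io import AlignedRead, ReferenceLocus

WT = 0
DONOR = 1


@dataclass(frozen=True)
class SNPVector:
    """Per-read donor-SNP states.

    ``states`` follows catalog order (ascending reference position);
    ``n_left`` counts left-arm SNPs so the per-arm outward orderings can be
    recovered. ``partial_coverage`` flags reads whose alignment does not span
    the full catalog (uncovered positions are scored WT).
    """

    read_id: str
    states: tuple[int, ...]
    n_left: int
    partial_coverage: bool = False

    @property
    def left_states(self) -> tuple[int, ...]:
        """Left-arm states ordered outward from the insertion."""
        return self.states[: self.n_left][::-1]

    @property
    def right_states(self) -> tuple[int, ...]:
        """Right-arm states ordered outward from the insertion."""
        return self.states[self.n_left :]


@dataclass(frozen=True)
class TractExtent:
    """Outermost incorporated-SNP |distance| per arm (0 = no incorporation)."""

    read_id: str
    left_extent: int
    right_extent: int


@dataclass
class TractSummary:
    """Aggregate tract statistics over GT reads (post-smoothing)."""

    per_snp: pd.DataFrame  # columns: distance, arm, ref_pos, pct_incorporated
    extents: list[TractExtent]
    n_gt_reads: int

    def extent_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.read_id, e.left_extent, e.right_extent) for e in self.extents],
            columns=["read_id", "left_extent", "right_extent"],
        )

    def hexbin_counts(self) -> pd.DataFrame:
        """(left_extent, right_extent) -> count table, hexbin/heatmap ready."""
        df = self.extent_frame()
        out = (
            df.groupby(["left_extent", "right_extent"])
            .size()
            .reset_index(name="count")
            .sort_values(["left_extent", "right_extent"])
            .reset_index(drop=True)
        )
        return out


def mark_snp_states(read: AlignedRead, spec: DonorSpec, locus: ReferenceLocus) -> SNPVector:
    """Score every cataloged SNP on one read as DONOR or WT.

    The read base aligned to each SNP reference position is located by a
    CIGAR walk. Only an exact donor-base match scores DONOR; the reference
    base, a third base, a deletion, or an uncovered position all score WT
    (binary states; the fill-in rule rescues interior miscalls).
    """
    if not spec.snps:
        raise SnpFreeDonorError("donor has no cataloged SNPs")
    positions = [s.ref_pos for s in spec.snps]
    bases: dict[int, str] = {}
    rpos = read.ref_start
    qpos = 0
    idx = 0
    n = len(positions)
    # advance catalog pointer past positions left of the alignment
    while idx < n and positions[idx] < rpos:
        idx += 1
    for op, ln in read.cigar:
        if op in ("M", "=", "X"):
            end = rpos + ln
            while idx < n and positions[idx] < end:
                p = positions[idx]
                bases[p] = read.query_sequence[qpos + (p - rpos)]
                idx += 1
            rpos = end
            qpos += ln
        elif op == "I":
            qpos += ln
        elif op in ("D", "N"):
            end = rpos + ln
            while idx < n and positions[idx] < end:
                idx += 1  # deleted SNP position: stays WT
            rpos = end
        elif op == "S":
            qpos += ln
    states = tuple(
        DONOR if bases.get(s.ref_pos) == s.donor_base else WT for s in spec.snps
    )
    covered = read.ref_start <= positions[0] and read.ref_end > positions[-1]
    n_left = sum(1 for s in spec.snps if s.arm == "left")
    return SNPVector(
        read_id=read.read_id,
        states=states,
        n_left=n_left,
        partial_coverage=not covered,
    )


def _smooth_arm(arm: Sequence[int], run_length: int) -> list[int]:
    s = list(arm)
    # truncation: everything external to the first run of `run_length`
    # consecutive WT states is forced WT (the run itself is kept WT)
    run = 0
    for i, st in enumerate(s):
        run = run + 1 if st == WT else 0
        if run == run_length:
            for j in range(i + 1, len(s)):
                s[j] = WT
            break
    # fill-in: WT positions inward of the outermost DONOR become DONOR
    outermost = -1
    for i, st in enumerate(s):
        if st == DONOR:
            outermost = i
    for i in range(outermost):
        s[i] = DONOR
    return s


def smooth_states(vec: SNPVector, run_length: int = 3) -> SNPVector:
    """Apply truncation then fill-in to each arm independently."""
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    left = _smooth_arm(vec.left_states, run_length)
    right = _smooth_arm(vec.right_states, run_length)
    states = tuple(left[::-1]) + tuple(right)
    return replace(vec, states=states)


def tract_extent(vec: SNPVector, spec: DonorSpec) -> TractExtent:
    """|distance| of the outermost DONOR SNP on each arm (0 if none)."""
    left_d = [abs(s.distance) for s in spec.snps[: vec.n_left]][::-1]
    right_d = [abs(s.distance) for s in spec.snps[vec.n_left :]]
    left = max(
        (d for d, st in zip(left_d, vec.left_states) if st == DONOR), default=0
    )
    right = max(
        (d for d, st in zip(right_d, vec.right_states) if st == DONOR), default=0
    )
    return TractExtent(read_id=vec.read_id, left_extent=left, right_extent=right)


def summarize_tracts(vectors: Iterable[SNPVector], spec: DonorSpec) -> TractSummary:
    """Per-SNP incorporation frequency and per-read extents over GT reads."""
    vectors = list(vectors)
    if not vectors:
        raise EmptyInputError("no GT reads to summarize")
    mat = np.array([v.states for v in vectors], dtype=np.int8)
    pct = 100.0 * mat.mean(axis=0)
    per_snp = pd.DataFrame(
        {
            "distance": [s.distance for s in spec.snps],
            "arm": [s.arm for s in spec.snps],
            "ref_pos": [s.ref_pos for s in spec.snps],
            "pct_incorporated": pct,
        }
    )
    extents = [tract_extent(v, spec) for v in vectors]
    return TractSummary(per_snp=per_snp, extents=extents, n_gt_reads=len(vectors))


def analyze_tracts(
    gt_reads: Iterable[AlignedRead],
    spec: DonorSpec,
    locus: ReferenceLocus,
    *,
    run_length: int = 3,
    include_partial: bool = True,
) -> TractSummary:
    """mark → smooth → summarize for a collection of GT-positive reads."""
    vectors = []
    for read in gt_reads:
        vec = mark_snp_states(read, spec, locus)
        if not include_partial and vec.partial_coverage:
            continue
        vectors.append(smooth_states(vec, run_length))
    return summarize_tracts(vectors, spec)
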