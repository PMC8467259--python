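"""Synthetic amplicon-read simulator with ground truth.

Emulates the study geometry: a reference amplicon with a centered nuclease
cut site, a donor with homology arms (default 500 bp) carrying a targeted
insertion (3 or 18 bp typical) and, optionally, engineered SNPs at fixed
spacing (30 or 50 bp typical) outward from the insertion. Reads are one of

* WT — the unmodified amplicon,
* GT — the amplicon with the donor insertion plus a per-arm conversion
  tract of incorporated donor SNPs drawn from a configurable tract model,
* background-indel — the amplicon with one "true mutagenesis" indel inside
  the target window, drawn from a small per-sample allele spectrum,

after which i.i.d. per-base substitution/insertion/deletion errors are
applied (defaults 3%/3%/4%, approximating long-read single-pass accuracy of
~90%). CIGARs are composed from the true edit script, so no external
aligner is needed, and every read carries a ground-truth record. All
randomness flows from a single integer seed; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from . import __version__
from .donor import DonorSpec, build_donor_spec
from .io import AlignedRead, ReferenceLocus, write_fasta

_ALPH = "ACGT"
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_OP2INT = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    ``tract_model`` is a per-arm distribution over the number of innermost
    SNPs incorporated: ``("geometric", p)`` draws m with P(m=k) = p(1-p)^k
    (truncated at the arm's SNP count), or ``("empirical", weights)`` with
    ``weights[k]`` the probability of incorporating exactly k innermost SNPs.
    ``n_indel_alleles`` controls how many distinct background-indel alleles
    the sample's spiked reads draw from (real nuclease samples are dominated
    by a few repair alleles).
    """

    seed: int = 0
    n_reads: int = 1000
    gt_fraction: float = 0.0
    indel_background_fraction: float = 0.0
    insertion_length: int = 18
    arm_length: int = 500
    flank: int = 0
    snp_spacing: Optional[int] = None
    tract_model: tuple = ("geometric", 0.5)
    n_indel_alleles: int = 1
    error_sub: float = 0.03
    error_ins: float = 0.03
    error_del: float = 0.04
    window_halfwidth: int = 4
    truncate_fraction: float = 0.0
    sample_id: str = "sim"
    locus_name: str = "amplicon"

    def __post_init__(self) -> None:
        for name in ("gt_fraction", "indel_background_fraction", "truncate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gt_fraction + self.indel_background_fraction > 1.0:
            raise ValueError("gt_fraction + indel_background_fraction > 1")
        for name in ("error_sub", "error_ins", "error_del"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.insertion_length < 1:
            raise ValueError("insertion_length must be >= 1")
        if self.arm_length < 1 or self.flank < 0:
            raise ValueError("invalid geometry")
        if self.snp_spacing is not None:
            if self.snp_spacing < 1 or self.snp_spacing > self.arm_length:
                raise ValueError("snp_spacing must be in [1, arm_length]")
            if self.snp_spacing <= self.window_halfwidth:
                raise ValueError("snp_spacing must exceed window_halfwidth")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.n_indel_alleles < 1:
            raise ValueError("n_indel_alleles must be >= 1")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["tract_model"] = list(self.tract_model[:1]) + [
            list(self.tract_model[1]) if isinstance(self.tract_model[1], (list, tuple, np.ndarray))
            else self.tract_model[1]
        ]
        return d


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    is_gt: bool
    true_left_extent: int
    true_right_extent: int
    has_background_indel: bool

    def __post_init__(self) -> None:
        if not self.is_gt and (self.true_left_extent or self.true_right_extent):
            raise ValueError("non-GT read with nonzero tract extent")


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPH[i] for i in rng.integers(0, 4, size=n))


def make_locus_and_donor(cfg: SimConfig) -> tuple[ReferenceLocus, str]:
    """Random reference (cut site centered) and matching donor sequence.

    The donor is the two homology arms copied from the reference with the
    targeted insertion at the cut site and, when ``snp_spacing`` is set,
    donor SNPs every ``snp_spacing`` bp outward from the insertion on both
    arms (distances ±k·spacing), skipping the indel target window.
    """
    rng = np.random.default_rng([int(cfg.seed), 11])
    length = 2 * (cfg.arm_length + cfg.flank)
    ref = _random_bases(rng, length)
    cut = cfg.flank + cfg.arm_length
    # redraw boundary bases that match the reference flanks so the insertion
    # placement is unambiguous (cannot be shifted left or right)
    insertion = _random_bases(rng, cfg.insertion_length)
    while insertion[-1] == ref[cut - 1] or insertion[0] == ref[cut]:
        insertion = _random_bases(rng, cfg.insertion_length)

    left = list(ref[cut - cfg.arm_length : cut])
    right = list(ref[cut : cut + cfg.arm_length])
    if cfg.snp_spacing is not None:
        k = 1
        while k * cfg.snp_spacing <= cfg.arm_length:
            d = k * cfg.snp_spacing
            if d > cfg.window_halfwidth:
                # left arm: distance -d -> ref position cut - d
                i = cfg.arm_length - d
                left[i] = _ALPH[(_IDX[left[i]] + int(rng.integers(1, 4))) % 4]
                # right arm: distance +d -> ref position cut + d - 1
                j = d - 1
                right[j] = _ALPH[(_IDX[right[j]] + int(rng.integers(1, 4))) % 4]
            k += 1
    donor = "".join(left) + insertion + "".join(right)
    locus = ReferenceLocus(
        name=cfg.locus_name,
        sequence=ref,
        cut_site=cut,
        window_halfwidth=cfg.window_halfwidth,
    )
    return locus, donor


def _draw_tract(rng: np.random.Generator, model: tuple, n_arm: int) -> int:
    """Number of innermost SNPs incorporated on one arm."""
    if n_arm == 0:
        return 0
    kind = model[0]
    if kind == "geometric":
        m = int(rng.geometric(float(model[1]))) - 1
    elif kind == "empirical":
        w = np.asarray(model[1], dtype=float)
        m = int(rng.choice(len(w), p=w / w.sum()))
    else:
        raise ValueError(f"unknown tract model {kind!r}")
    return min(m, n_arm)


def _merge_push(cig: list[list], op: str, ln: int) -> None:
    if ln <= 0:
        return
    if cig and cig[-1][0] == op:
        cig[-1][1] += ln
    else:
        cig.append([op, ln])


def apply_errors(
    query: str,
    cigar: Sequence[tuple[str, int]],
    rng: np.random.Generator,
    p_sub: float,
    p_ins: float,
    p_del: float,
) -> tuple[str, tuple[tuple[str, int], ...], int]:
    """Apply i.i.d. per-base errors to a true alignment.

    Each query base is independently deleted (``p_del``) or substituted to a
    uniformly chosen different base (``p_sub``); after each surviving base a
    geometric-length insertion of random bases starts with probability
    ``p_ins``. The CIGAR is recomposed from the edit script; leading/trailing
    deletions are trimmed (returned as a reference-start shift).

    Returns ``(new_query, new_cigar, ref_start_shift)``.
    """
    n = len(query)
    if n == 0 or (p_sub == 0 and p_ins == 0 and p_del == 0):
        return query, tuple((op, ln) for op, ln in cigar), 0
    dele = rng.random(n) < p_del
    sub = (rng.random(n) < p_sub) & ~dele
    ins = (rng.random(n) < p_ins) & ~dele
    n_sub = int(sub.sum())
    sub_off = rng.integers(1, 4, size=n_sub) if n_sub else None
    n_ins = int(ins.sum())
    if n_ins:
        ins_len = rng.geometric(1.0 - p_ins, size=n_ins)
        ins_bases = rng.integers(0, 4, size=int(ins_len.sum()))
    else:
        ins_len = ins_bases = None

    out_q: list[str] = []
    out_c: list[list] = []
    qi = si = ii = bi = 0
    for op, ln in cigar:
        if op in ("M", "=", "X", "I"):
            emit = "M" if op in ("M", "=", "X") else "I"
            for _ in range(ln):
                if dele[qi]:
                    if emit == "M":
                        _merge_push(out_c, "D", 1)
                    # a deleted inserted base simply vanishes
                else:
                    b = query[qi]
                    if sub[qi]:
                        b = _ALPH[(_IDX.get(b, 0) + int(sub_off[si])) % 4]
                        si += 1
                    out_q.append(b)
                    _merge_push(out_c, emit, 1)
                if ins[qi]:
                    ln_i = int(ins_len[ii])
                    ii += 1
                    for _ in range(ln_i):
                        out_q.append(_ALPH[int(ins_bases[bi])])
                        bi += 1
                    _merge_push(out_c, "I", ln_i)
                qi += 1
        elif op in ("D", "N"):
            _merge_push(out_c, "D", ln)
        else:
            raise ValueError(f"unexpected CIGAR op in true alignment: {op}")

    shift = 0
    while out_c and out_c[0][0] == "D":
        shift += out_c.pop(0)[1]
    while out_c and out_c[-1][0] == "D":
        out_c.pop()
    return "".join(out_q), tuple((op, ln) for op, ln in out_c), shift


def _true_read(
    cfg: SimConfig,
    locus: ReferenceLocus,
    spec: DonorSpec,
    category: str,
    rng: np.random.Generator,
    alleles: list,
    span: tuple[int, int],
) -> tuple[str, list[tuple[str, int]], int, int, int, bool]:
    """Build the error-free read for one category.

    Returns (query, cigar, ref_start, left_extent, right_extent, has_bg).
    """
    ref = locus.sequence
    c = locus.cut_site
    s0, s1 = span
    if category == "wt":
        return ref[s0:s1], [("M", s1 - s0)], s0, 0, 0, False
    if category == "gt":
        left_snps = spec.left_snps
        right_snps = spec.right_snps
        m_l = _draw_tract(rng, cfg.tract_model, len(left_snps))
        m_r = _draw_tract(rng, cfg.tract_model, len(right_snps))
        seq = list(ref[s0:s1])
        for snp in left_snps[:m_l]:
            if s0 <= snp.ref_pos < s1:
                seq[snp.ref_pos - s0] = snp.donor_base
        for snp in right_snps[:m_r]:
            if s0 <= snp.ref_pos < s1:
                seq[snp.ref_pos - s0] = snp.donor_base
        query = "".join(seq[: c - s0]) + spec.insertion_sequence + "".join(seq[c - s0 :])
        cigar = []
        if c - s0 > 0:
            cigar.append(("M", c - s0))
        cigar.append(("I", len(spec.insertion_sequence)))
        if s1 - c > 0:
            cigar.append(("M", s1 - c))
        l_ext = abs(left_snps[m_l - 1].distance) if m_l else 0
        r_ext = abs(right_snps[m_r - 1].distance) if m_r else 0
        return query, cigar, s0, l_ext, r_ext, False
    # background indel
    vtype, pos, length, ins_seq = alleles[int(rng.integers(0, len(alleles)))]
    if vtype == "insertion":
        query = ref[s0:pos] + ins_seq + ref[pos:s1]
        cigar = []
        if pos - s0 > 0:
            cigar.append(("M", pos - s0))
        cigar.append(("I", length))
        if s1 - pos > 0:
            cigar.append(("M", s1 - pos))
    else:
        query = ref[s0:pos] + ref[pos + length : s1]
        cigar = [
            (op, ln)
            for op, ln in (("M", pos - s0), ("D", length), ("M", s1 - pos - length))
            if ln > 0
        ]
    return query, cigar, s0, 0, 0, True


def _draw_alleles(cfg: SimConfig, locus: ReferenceLocus, rng: np.random.Generator) -> list:
    """Per-sample background-indel allele spectrum.

    Alleles are ≥2 bp: single-base alleles are indistinguishable from the
    platform's per-base indel error at realistic depths, so the generator
    models the separable part of a nuclease's repair spectrum.
    """
    c, w = locus.cut_site, locus.window_halfwidth
    alleles = []
    for _ in range(cfg.n_indel_alleles):
        vtype = "insertion" if rng.random() < 0.5 else "deletion"
        length = 2 + min(int(rng.geometric(0.5)) - 1, 18)
        if vtype == "insertion":
            pos = int(rng.integers(c - w, c + w + 1))
            seq = _random_bases(rng, length)
        else:
            lo = max(1, c - w - length + 1)
            pos = int(rng.integers(lo, c + w + 1))
            pos = min(pos, len(locus.sequence) - length - 1)
            seq = ""
        alleles.append((vtype, pos, length, seq))
    return alleles


def simulate_reads(
    cfg: SimConfig,
    locus: ReferenceLocus,
    spec: DonorSpec,
    sam_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[AlignedRead], list[TruthRecord]]:
    """Simulate the sample; optionally write SAM + truth TSV.

    Reads are emitted in coordinate-sorted order in the SAM; the returned
    lists keep generation order (read ids are stable either way).
    """
    rng = np.random.default_rng([int(cfg.seed), 23])
    ref_len = len(locus.sequence)
    c, w = locus.cut_site, locus.window_halfwidth
    alleles = (
        _draw_alleles(cfg, locus, rng) if cfg.indel_background_fraction > 0 else []
    )

    reads: list[AlignedRead] = []
    truths: list[TruthRecord] = []
    p_gt = cfg.gt_fraction
    p_bg = cfg.indel_background_fraction
    for i in range(cfg.n_reads):
        u = rng.random()
        if u < p_gt:
            category = "gt"
        elif u < p_gt + p_bg:
            category = "bg"
        else:
            category = "wt"
        span = (0, ref_len)
        if cfg.truncate_fraction > 0 and rng.random() < cfg.truncate_fraction:
            # one-sided truncation that always retains the target window
            margin = 10
            if rng.random() < 0.5 and c - w - margin > 1:
                span = (int(rng.integers(1, c - w - margin)), ref_len)
            elif c + w + margin < ref_len - 1:
                span = (0, int(rng.integers(c + w + margin + 1, ref_len)))
        query, cigar, ref_start, l_ext, r_ext, has_bg = _true_read(
            cfg, locus, spec, category, rng, alleles, span
        )
        query, cigar, shift = apply_errors(
            query, cigar, rng, cfg.error_sub, cfg.error_ins, cfg.error_del
        )
        read_id = f"{cfg.sample_id}_read{i:06d}"
        reads.append(
            AlignedRead(
                read_id=read_id,
                sample_id=cfg.sample_id,
                ref_start=ref_start + shift,
                cigar=cigar,
                query_sequence=query,
                is_mapped=True,
                mapq=60,
            )
        )
        truths.append(
            TruthRecord(
                read_id=read_id,
                is_gt=category == "gt",
                true_left_extent=l_ext,
                true_right_extent=r_ext,
                has_background_indel=has_bg,
            )
        )

    if sam_path is not None:
        write_sam(sam_path, locus, reads, sample_id=cfg.sample_id)
    if truth_path is not None:
        write_truth(truth_path, truths)
    return reads, truths


def write_sam(
    path: str | Path,
    locus: ReferenceLocus,
    reads: Sequence[AlignedRead],
    *,
    sample_id: str = "sim",
) -> None:
    """Write coordinate-sorted SAM with RG/PG header lines (deterministic)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": locus.name, "LN": len(locus.sequence)}],
            "RG": [{"ID": sample_id, "SM": sample_id}],
            "PG": [{"ID": "gentract", "PN": "gentract", "VN": __version__}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in sorted(reads, key=lambda r: r.ref_start):
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.read_id
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = read.ref_start
            seg.mapping_quality = read.mapq
            seg.cigartuples = [(_OP2INT[op], ln) for op, ln in read.cigar]
            seg.query_sequence = read.query_sequence
            seg.set_tag("RG", read.sample_id)
            out.write(seg)


def write_truth(path: str | Path, truths: Sequence[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tis_gt\ttrue_left_extent\ttrue_right_extent\thas_background_indel\n"
        )
        for t in truths:
            fh.write(
                f"{t.read_id}\t{int(t.is_gt)}\t{t.true_left_extent}\t"
                f"{t.true_right_extent}\t{int(t.has_background_indel)}\n"
            )


def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a complete dataset on disk.

    Writes ``reference.fasta``, ``donor.fasta``, ``reads.sam``, ``truth.tsv``
    and ``config.json`` into ``out_dir`` and returns their paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    locus, donor = make_locus_and_donor(cfg)
    spec = build_donor_spec(donor, locus)
    paths = {
        "reference": out_dir / "reference.fasta",
        "donor": out_dir / "donor.fasta",
        "sam": out_dir / "reads.sam",
        "truth": out_dir / "truth.tsv",
        "config": out_dir / "config.json",
    }
    write_fasta(paths["reference"], locus.name, locus.sequence)
    write_fasta(paths["donor"], f"{locus.name}_donor", donor)
    simulate_reads(cfg, locus, spec, sam_path=paths["sam"], truth_path=paths["truth"])
    paths["config"].write_text(
        json.dumps(cfg.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    return paths
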