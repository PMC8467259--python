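# Methods

## Problem and model

`gentract` quantifies the outcomes of a nuclease + donor gene-targeting (GT)
experiment from long-read amplicon sequencing. Long reads span amplicons of
several kilobases, which lets primers sit outside the donor homology arms
(avoiding donor amplification artifacts) and preserves phase across an
entire homology arm — but single-pass long reads carry a high per-base error
rate, so every statistic the package computes includes an explicit
error-accommodation step.

The package consumes reads already aligned to the amplicon reference
(e.g. by minimap2); basecalling, demultiplexing and alignment are outside
its scope. All coordinates are 0-based, half-open internally; the sole
conversion from SAM's 1-based POS happens at load time.

Three analyses share one geometric model: a reference amplicon with a
predicted nuclease cut site, and a donor of the form
`LHA + insertion + RHA` — two homology arms copied from the reference
(optionally carrying SNPs) flanking a single targeted insertion at the cut
site.

### Targeted mutagenesis

A CIGAR walk extracts every insertion and deletion that intersects the
*target window*, the closed ±4 bp interval around the cut site (insertions
intersect when their anchor lies in the window; deletions when their
reference interval overlaps it). Variants are keyed by
`(type, position, length)` — deliberately not by inserted sequence, which
per-base error would fragment. A read contributes at most one count per
distinct key.

Because per-base error also produces window indels, a matched no-nuclease
control is tabulated with identical rules and subtracted key-by-key. Keys
whose post-subtraction frequency exceeds a threshold (default 0.5%) sum to
the *adjusted targeted mutagenesis frequency*. Two readings of the
threshold sentence are possible (pre- vs post-subtraction frequencies); we
threshold the post-subtraction difference, which makes the
treated-equals-control identity exact. Without a control the computation
degenerates to thresholding raw frequencies and is prominently flagged,
since it then includes platform error.

Consequences worth knowing: (i) a diffuse indel spectrum spread over many
sub-threshold keys is invisible to this estimator — that is a property of
the published rule, not of this implementation; (ii) sampling noise can
push an error-driven key's difference above the threshold, adding a small
positive bias that shrinks with control depth (hence deep controls are
recommended; see *Verification* below).

### Gene targeting

A read is GT-positive when the concatenation of its window insertions (long
reads fragment long insertions into several CIGAR `I` runs) is within a
Levenshtein distance of ⌊L/3⌋ of the expected L bp donor insertion — 6
edits for 18 bp, 1 for 3 bp, exact match below 3 bp. Distance is computed
by the standard unit-cost dynamic program. The fractional cap absorbs
errors inside the insertion while error-induced candidates (typically 1–3
bp) remain far beyond it, which keeps the false-positive rate effectively
zero: for a candidate of length c, the distance is at least 18 − c, so a
spurious call would need ≥ 12 error-inserted bases inside a 9-position
window.

By default GT-positive reads are excluded from the mutagenesis tables (the
donor insertion is a targeting outcome, not imprecise repair; counting it
twice would inflate both statistics). A flag restores them.

### Conversion tracts

The donor model is derived by pairwise alignment of donor to reference
(match +1, mismatch −1, gap open −4, extend −1; reference end gaps free).
The single donor-only gap is the insertion, left-aligned as in standard
variant normalization so its coordinate is deterministic; every arm
mismatch becomes a cataloged SNP with a signed distance from the insertion
(−1/+1 are the flanking bases, so the catalog mirrors exactly under reverse
complement). Single-arm donors are recovered through a local-alignment
fallback — the global DP cannot leave a donor and a reference overhang at
the same end — with mismatch-dense arm edges peeled back into the
insertion; a few insertion-edge bases that match the reference by chance
may still be absorbed into the arm, an inherent boundary ambiguity of
single-arm designs.

For each GT-positive read, the base aligned to each SNP position is scored
DONOR (exact donor-base match) or WT (reference base, third base, deletion,
or uncovered — binary states, conservatively). Two smoothing rules then run
per arm, scanning outward from the insertion:

1. **truncation** — every SNP external to the first run of 3 consecutive
   WT calls is forced WT;
2. **fill-in** — WT calls inward of the outermost surviving DONOR call are
   set DONOR.

The result is always a contiguous DONOR prefix per arm; the tract extent is
the |distance| of the outermost DONOR SNP. Smoothing is idempotent.
Residual background survives essentially only at the innermost SNPs: with
~1% per-SNP miscall (3% substitution error, one of three alternative
bases), a spurious call beyond the third SNP requires two correlated
miscalls without an intervening 3-WT run, ~6×10⁻⁴ per read-arm (verified
by exact enumeration and simulation). Third-base and uncovered positions
scoring WT is deliberate: fill-in rescues interior miscalls, and the
binary state space matches the present/absent bookkeeping of the method.

## Simulator

The simulator generates ground-truth-annotated SAM datasets with the study
geometry: 500 bp homology arms (configurable), a 3 or 18 bp insertion at a
centered cut site, and optional engineered SNPs every 30 or 50 bp outward
from the insertion (skipping the indel window). Reads are WT, GT, or
background-indel:

* GT reads carry the exact insertion plus a per-arm conversion tract: the
  number of innermost SNPs incorporated is drawn from a configurable tract
  model, by default geometric — P(m = k) = p(1−p)^k truncated at the arm's
  SNP count — so the per-SNP incorporation frequency has the closed-form
  survival (1−p)^k used as the analytic oracle in tests.
* Background-indel reads model true (nuclease-induced) imprecise repair:
  each sample draws a small allele spectrum (default one allele, matching
  the common case of a dominant repair allele) of window indels of ≥ 2 bp.
  Single-base alleles are excluded from the default spectrum because they
  coincide with the platform's per-base indel error keys and are not
  separable by the subtraction-plus-threshold rule at realistic depths.

Errors are applied post-construction as i.i.d. per-base events: deletion
4%, substitution 3% (uniform over the three alternatives), and after each
surviving base a geometric-length insertion starting with probability 3% —
approximating ~90% single-pass accuracy. The CIGAR is recomposed from the
true edit script, so no external aligner is needed and every emitted record
satisfies the package's CIGAR/query consistency checks. Real long-read
error is context-dependent (homopolymers above all); the i.i.d. model is
deliberately simpler — it exercises every robustness rule in the pipeline,
but passing tests say nothing about homopolymer-clustered miscalls, and
real data may show locally correlated SNP miscalls that the smoothing rules
see more often than the i.i.d. rate predicts.

All randomness flows from one integer seed through fixed-tag
`numpy.random.Generator` streams; identical configurations produce
byte-identical FASTA/SAM/TSV outputs.

## Numerical and design choices

* `min_mapq` defaults to 1 (drop only multimappers); the method states no
  mapping-quality filter, so the filter is configurable and every dropped
  read is counted in the logged filter statistics.
* Fractional Ld thresholds round down, consistent with both printed anchor
  points (18 → 6, 3 → 1) and conservative in between.
* Window membership: insertions by closed-interval anchor, deletions by
  interval overlap with the closed window.
* The truncation rule keeps the 3-WT run itself WT and forces only
  positions strictly beyond it; fill-in sets *all* interior WT positions,
  not just isolated singletons. Truncation scans outward from the
  insertion, consistent with background being retained only at the
  innermost SNPs.
* Degenerate inputs raise typed errors rather than warning: header/locus
  mismatches, SNP-free donors in tract analysis, empty read sets, and
  donors without a recoverable single insertion are all hard failures.

## Verification scale

Test and acceptance runs use problem sizes chosen to make binomial
tolerances meaningful on one CPU: 50,000 reads for the false-positive
bound; 10,000 treated reads (with a 50,000-read shared control — controls
are shared across samples, so sequencing them deeper is standard practice)
for recovery of GT and mutagenesis fractions at 2/10/30% within 3 binomial
standard errors; 2,500 reads for background confinement (< 0.2% of
read-arms with any post-smoothing DONOR call beyond the 3 innermost SNPs,
versus ~6×10⁻⁴ expected); 5,000 error-free reads for the geometric-tract
survival check. The Levenshtein implementation is checked exhaustively
against a memoized recursive oracle for all DNA pairs up to length 4 and on
seeded samples up to length 7 (and against edlib as a third
implementation).

## Known limitations

* Donors encoding deletions or substitution-only edits are rejected; only
  single-insertion donors are modeled.
* No UMI deduplication: read counts, not molecule counts.
* The mutagenesis estimator inherits the published rule's blind spot for
  diffuse sub-threshold indel spectra and its small positive bias from
  threshold-crossing noise.
* Tract analysis reports extents; it does not classify repair sub-pathways
  (SDSA vs dHJ) or detect crossovers/heteroduplexes.
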