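"""SNP phasing, tract smoothing rules, and tract summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gentract as g
from gentract.tracts import _smooth_arm
from conftest import make_read

W, D = g.WT, g.DONOR


def _vec(left, right, read_id="r"):
    """Build an SNPVector from per-arm outward-ordered state lists."""
    return g.SNPVector(
        read_id=read_id, states=tuple(left[::-1]) + tuple(right), n_left=len(left)
    )


class TestMarkSnpStates:
    def _gt_read(self, locus, spec, m_left, m_right, read_id="r"):
        c = locus.cut_site
        seq = list(locus.sequence)
        for snp in spec.left_snps[:m_left]:
            seq[snp.ref_pos] = snp.donor_base
        for snp in spec.right_snps[:m_right]:
            seq[snp.ref_pos] = snp.donor_base
        ins = spec.insertion_sequence
        q = "".join(seq[:c]) + ins + "".join(seq[c:])
        return make_read(
            0, [("M", c), ("I", len(ins)), ("M", len(locus) - c)], q, read_id=read_id
        )

    def test_full_donor_read_all_donor(self, snp_bundle):
        _, locus, _, spec = snp_bundle
        read = self._gt_read(locus, spec, 6, 6)
        vec = g.mark_snp_states(read, spec, locus)
        assert set(vec.states) == {D}
        assert not vec.partial_coverage

    def test_bare_insertion_read_all_wt(self, snp_bundle):
        _, locus, _, spec = snp_bundle
        read = self._gt_read(locus, spec, 0, 0)
        vec = g.mark_snp_states(read, spec, locus)
        assert set(vec.states) == {W}

    def test_deleted_snp_position_scores_wt(self, snp_bundle):
        _, locus, _, spec = snp_bundle
        read = self._gt_read(locus, spec, 6, 6)
        # delete 3 bp spanning the innermost right-arm SNP
        snp = spec.right_snps[0]
        p = snp.ref_pos
        q = read.query_sequence
        qpos = p + len(spec.insertion_sequence)  # read covers ins before snp
        read2 = make_read(
            0,
            [
                ("M", locus.cut_site),
                ("I", len(spec.insertion_sequence)),
                ("M", p - locus.cut_site),
                ("D", 3),
                ("M", len(locus) - p - 3),
            ],
            q[: qpos - read.ref_start] + q[qpos + 3 - read.ref_start :],
            read_id="del",
        )
        vec = g.mark_snp_states(read2, spec, locus)
        i = spec.snps.index(snp)
        assert vec.states[i] == W
        others = [s for j, s in enumerate(vec.states) if j != i]
        assert set(others) == {D}

    def test_third_base_scores_wt(self, snp_bundle):
        _, locus, _, spec = snp_bundle
        read = self._gt_read(locus, spec, 6, 6)
        snp = spec.left_snps[2]
        third = next(b for b in "ACGT" if b not in (snp.ref_base, snp.donor_base))
        q = list(read.query_sequence)
        q[snp.ref_pos] = third  # left arm: query index == ref index
        vec = g.mark_snp_states(
            make_read(0, read.cigar, "".join(q)), spec, locus
        )
        assert vec.states[spec.snps.index(snp)] == W

    def test_partial_coverage_flagged(self, snp_bundle):
        _, locus, _, spec = snp_bundle
        c = locus.cut_site
        start = spec.snps[1].ref_pos + 1  # starts past the outermost left SNP
        q = locus.sequence[start:c] + spec.insertion_sequence + locus.sequence[c:]
        read = make_read(
            start,
            [("M", c - start), ("I", len(spec.insertion_sequence)), ("M", len(locus) - c)],
            q,
        )
        vec = g.mark_snp_states(read, spec, locus)
        assert vec.partial_coverage
        assert vec.states[0] == W  # uncovered position scores WT


class TestSmoothStates:
    def test_truncation_beyond_first_wt_run(self):
        vec = _vec([D, W, W, W, D], [])
        out = g.smooth_states(vec)
        assert out.left_states == (D, W, W, W, W)

    def test_truncation_then_fill_in(self):
        vec = _vec([D, W, D, W, W, W, D], [])
        out = g.smooth_states(vec)
        assert out.left_states == (D, D, D, W, W, W, W)

    def test_all_wt_unchanged(self):
        vec = _vec([W] * 6, [W] * 6)
        out = g.smooth_states(vec)
        assert out.states == vec.states

    def test_arms_independent(self):
        vec = _vec([D, W, W, W, D], [D, D, W, D, W])
        out = g.smooth_states(vec)
        assert out.left_states == (D, W, W, W, W)
        assert out.right_states == (D, D, D, D, W)

    def test_run_length_validation(self):
        with pytest.raises(ValueError):
            g.smooth_states(_vec([D], [D]), run_length=0)

    arm = st.lists(st.integers(0, 1), min_size=0, max_size=12)

    @given(arm, arm)
    def test_idempotent(self, left, right):
        vec = _vec(left, right)
        once = g.smooth_states(vec)
        assert g.smooth_states(once).states == once.states

    @given(arm, arm)
    def test_smoothed_arms_are_prefixes(self, left, right):
        """After smoothing, each arm's DONOR set is a contiguous prefix that
        does not extend past the first 3-WT run of the raw arm."""
        out = g.smooth_states(_vec(left, right))
        for raw, states in ((left, out.left_states), (right, out.right_states)):
            seen_wt = False
            for stt in states:
                if stt == W:
                    seen_wt = True
                else:
                    assert not seen_wt  # prefix property
            n_donor = sum(1 for stt in states if stt == D)
            # find first 3-WT run in the raw arm
            run = 0
            limit = len(raw)
            for i, stt in enumerate(raw):
                run = run + 1 if stt == W else 0
                if run == 3:
                    limit = i - 2  # first index of the run
                    break
            assert n_donor <= limit


class TestTractExtent:
    def test_no_donor_states(self, snp_bundle):
        _, _, _, spec = snp_bundle
        e = g.tract_extent(_vec([W] * 6, [W] * 6), spec)
        assert (e.left_extent, e.right_extent) == (0, 0)

    def test_one_sided_extent(self, snp_bundle):
        _, _, _, spec = snp_bundle
        # left arm DONOR out to the 3rd SNP (distance -150), right arm none
        e = g.tract_extent(_vec([D, D, D, W, W, W], [W] * 6), spec)
        assert (e.left_extent, e.right_extent) == (150, 0)

    def test_full_tract_extent(self, snp_bundle):
        _, _, _, spec = snp_bundle
        e = g.tract_extent(_vec([D] * 6, [D] * 6), spec)
        assert (e.left_extent, e.right_extent) == (300, 300)


class TestSummarizeTracts:
    def test_all_full_tracts(self, snp_bundle):
        _, _, _, spec = snp_bundle
        vs = [_vec([D] * 6, [D] * 6, read_id=f"r{i}") for i in range(10)]
        s = g.summarize_tracts(vs, spec)
        assert (s.per_snp["pct_incorporated"] == 100.0).all()
        assert s.n_gt_reads == 10

    def test_half_and_half(self, snp_bundle):
        _, _, _, spec = snp_bundle
        vs = [_vec([D] * 6, [D] * 6, read_id=f"f{i}") for i in range(5)]
        vs += [_vec([W] * 6, [W] * 6, read_id=f"z{i}") for i in range(5)]
        s = g.summarize_tracts(vs, spec)
        assert (s.per_snp["pct_incorporated"] == 50.0).all()
        counts = {(r.left_extent, r.right_extent) for r in s.extents}
        assert counts == {(0, 0), (300, 300)}
        hx = s.hexbin_counts()
        assert sorted(hx["count"]) == [5, 5]

    def test_empty_input_raises(self, snp_bundle):
        _, _, _, spec = snp_bundle
        with pytest.raises(g.EmptyInputError):
            g.summarize_tracts([], spec)


def test_geometric_tracts_match_survival_function(snp_bundle):
    """Error-free GT reads with geometric tract draws: per-SNP incorporation
    equals the geometric survival function (1-p)^k within 3 binomial SE."""
    _, locus, _, spec = snp_bundle
    p = 0.5
    n = 5000
    cfg = g.SimConfig(
        seed=21, n_reads=n, gt_fraction=1.0, snp_spacing=50, arm_length=300,
        flank=40, tract_model=("geometric", p),
        error_sub=0.0, error_ins=0.0, error_del=0.0,
    )
    reads, _ = g.simulate_reads(cfg, locus, spec)
    summary = g.analyze_tracts(reads, spec, locus)
    for _, row in summary.per_snp.iterrows():
        k = abs(row["distance"]) // 50  # SNP index from the insertion, 1-based
        expect = (1 - p) ** k
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(row["pct_incorporated"] / 100 - expect) <= 3 * se + 1e-9
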