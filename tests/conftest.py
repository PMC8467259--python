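import pytest
from hypothesis import HealthCheck, settings

import gentract as g

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=150,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_read(ref_start, cigar, query, read_id="r1", sample_id="s1", mapq=60):
    return g.AlignedRead(
        read_id=read_id,
        sample_id=sample_id,
        ref_start=ref_start,
        cigar=tuple(cigar),
        query_sequence=query,
        mapq=mapq,
    )


@pytest.fixture(scope="session")
def snp_bundle():
    """Locus + SNP-bearing donor (18 bp insertion, SNPs every 50 bp)."""
    cfg = g.SimConfig(
        seed=5, n_reads=10, gt_fraction=0.5, snp_spacing=50,
        insertion_length=18, arm_length=300, flank=40,
    )
    locus, donor = g.make_locus_and_donor(cfg)
    spec = g.build_donor_spec(donor, locus)
    return cfg, locus, donor, spec


@pytest.fixture(scope="session")
def plain_bundle():
    """Locus + perfect-homology donor (no SNPs), 1 kb reference."""
    cfg = g.SimConfig(seed=6, n_reads=10, insertion_length=18, arm_length=500)
    locus, donor = g.make_locus_and_donor(cfg)
    spec = g.build_donor_spec(donor, locus)
    return cfg, locus, donor, spec
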