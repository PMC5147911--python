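import numpy as np
import pytest

from mitomix import (
    ErrorProfile,
    generate_haplotypes,
    generate_reference,
    simulate_mixture,
    simulate_short_reads,
)
from mitomix.pipeline import PipelineConfig, run_pipeline
from mitomix.reads import AlignedRead, parse_cigar

PHASING_REGIONS = [(1000, 8000), (10000, 15000)]


@pytest.fixture(scope="session")
def ref():
    return generate_reference(16569, 3, 6, seed=7)


@pytest.fixture(scope="session")
def haps(ref):
    return generate_haplotypes(
        ref, 31, 6, 1, seed=1, private_regions=PHASING_REGIONS
    )


@pytest.fixture(scope="session")
def zero_profile():
    return ErrorProfile.zero()


@pytest.fixture(scope="session")
def clean_pairs_a(ref, haps):
    """Zero-error single-source short reads for contributor A at 60x."""
    return simulate_short_reads(
        ref, haps[0], 60, profile=ErrorProfile.zero(), seed=3
    )


@pytest.fixture(scope="session")
def clean_mixture(ref, haps):
    """Zero-error 1:1 mixture: 400x short, 120x long, all molecules full."""
    return simulate_mixture(
        ref, haps[0], haps[1], (0.5, 0.5),
        short_depth=400, long_depth=120,
        short_profile=ErrorProfile.zero(), long_profile=ErrorProfile.zero(),
        truncated_fraction=0.0, seed=9,
    )


@pytest.fixture(scope="session")
def small_ref():
    """A 3 kb genome with proportionally scaled amplicons, for deep fixtures."""
    return generate_reference(3000, 1, 6, seed=13)


@pytest.fixture(scope="session")
def small_haps(small_ref):
    return generate_haplotypes(small_ref, 5, 3, 1, seed=13)


@pytest.fixture(scope="session")
def deep_clean_mixture_small(small_ref, small_haps):
    """Zero-error 1:1 mixture at 6000x short coverage: deep enough that the
    half-VAF expectation at private SNPs holds within +/- 0.03."""
    return simulate_mixture(
        small_ref, small_haps[0], small_haps[1], (0.5, 0.5),
        short_depth=6000, long_depth=0,
        short_profile=ErrorProfile.zero(), long_profile=ErrorProfile.zero(),
        seed=9,
    )


@pytest.fixture(scope="session")
def full_run():
    """One full-depth pipeline run under the default study conditions."""
    return run_pipeline(PipelineConfig(seed=1001), write_outputs=False)


@pytest.fixture
def mk_read():
    """Factory for hand-built aligned reads in tests."""

    counter = [0]

    def factory(ref_start, cigar, seq, platform="LONG", **kwargs):
        counter[0] += 1
        kwargs.setdefault("read_id", f"test_{counter[0]:03d}")
        return AlignedRead(
            platform=platform,
            ref_start=ref_start,
            cigar=parse_cigar(cigar) if isinstance(cigar, str) else cigar,
            seq=seq,
            quals=np.full(len(seq), 30, dtype=np.uint8),
            **kwargs,
        )

    return factory


def haplotype_base(ref, hap, pos):
    """Truth base of a haplotype at a reference position (SNPs only)."""
    for v in hap.all_variants:
        if v.pos == pos and v.vclass == "SNP":
            return v.alt_allele
    return ref.sequence[pos]
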