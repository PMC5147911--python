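"""Simulator contracts: determinism, alignment consistency, coverage,
error-model behaviour and mixture proportions."""

import numpy as np
import pytest

from mitomix import (
    ErrorProfile,
    build_pileup,
    generate_haplotypes,
    generate_reference,
    simulate_long_reads,
    simulate_mixture,
    simulate_short_reads,
    vaf,
)
from mitomix.reads import validate_reads
from mitomix.simdata import ConfigurationError, SizingError

from conftest import PHASING_REGIONS


class TestGenerateReference:
    def test_planted_runs_match_sequence_and_count(self):
        ref = generate_reference(16569, 3, 6, seed=7)
        assert len(ref) == 16569
        assert len(ref.homopolymers) == 3
        for start, run, base in ref.homopolymers:
            assert run >= 6
            assert ref.sequence[start : start + run] == base * run
            # maximal: flanks break the run
            assert ref.sequence[start - 1] != base
            assert ref.sequence[start + run] != base

    def test_no_runs_requested_gives_empty_annotation(self):
        ref = generate_reference(16569, 0, 6, seed=7)
        assert ref.homopolymers == []

    def test_deterministic_for_fixed_seed(self):
        a = generate_reference(16569, 3, 6, seed=7)
        b = generate_reference(16569, 3, 6, seed=7)
        assert a.sequence == b.sequence
        assert a.homopolymers == b.homopolymers
        c = generate_reference(16569, 3, 6, seed=8)
        assert c.sequence != a.sequence

    def test_amplicons_cover_genome_with_interior_overlap(self):
        ref = generate_reference(16569, 3, 6, seed=7)
        amp_a, amp_b = ref.amplicons
        assert amp_a.start == 0 and amp_b.end == len(ref)
        assert amp_b.start < amp_a.end  # overlap
        # sizes within 10% of the 8.6/8.3 kb design
        assert abs(amp_a.length - 8600) <= 860
        assert abs(amp_b.length - 8300) <= 830
        covered = np.zeros(len(ref), dtype=bool)
        for amp in ref.amplicons:
            covered[amp.start : amp.end] = True
        assert covered.all()

    def test_too_small_genome_raises(self):
        with pytest.raises(SizingError):
            generate_reference(500, 0, 6, seed=1)


class TestGenerateHaplotypes:
    def test_backbone_shared_and_privates_disjoint(self, ref):
        hap_a, hap_b = generate_haplotypes(ref, 5, 2, 0, seed=1)
        assert {(v.pos, v.alt_allele) for v in hap_a.shared_variants} == {
            (v.pos, v.alt_allele) for v in hap_b.shared_variants
        }
        pa = {v.pos for v in hap_a.private_variants}
        pb = {v.pos for v in hap_b.private_variants}
        shared = {v.pos for v in hap_a.shared_variants}
        assert not pa & pb
        assert not (pa | pb) & shared

    def test_study_design_counts(self, haps):
        hap_a, hap_b = haps
        assert len(hap_a.shared_variants) == 31
        snps = [v for v in hap_a.private_variants if v.vclass == "SNP"]
        ins = [v for v in hap_a.private_variants if v.vclass == "INS"]
        assert (len(snps), len(ins)) == (6, 1)
        union_private = hap_a.private_variants + hap_b.private_variants
        assert sum(v.vclass == "SNP" for v in union_private) == 12
        assert sum(v.vclass == "INS" for v in union_private) == 2

    def test_one_private_snp_sits_in_a_homopolymer_run(self, ref, haps):
        runs = [range(s, s + n) for s, n, _ in ref.homopolymers]
        in_run = [
            v
            for v in haps[0].private_variants
            if v.vclass == "SNP" and any(v.pos in r for r in runs)
        ]
        assert in_run

    def test_no_variant_case(self, ref):
        hap_a, hap_b = generate_haplotypes(ref, 0, 0, 0, seed=1)
        assert hap_a.all_variants == [] and hap_b.all_variants == []

    def test_private_regions_respected(self, haps):
        for hap in haps:
            for v in hap.private_variants:
                assert any(lo <= v.pos < hi for lo, hi in PHASING_REGIONS)


class TestShortReads:
    def test_mean_coverage_near_requested_depth(self, ref, haps, clean_pairs_a):
        from mitomix.reconstruct import coverage_track

        depth = coverage_track(clean_pairs_a, ref)
        # amplicon interiors, away from fragment-length ramps
        amp_a, amp_b = ref.amplicons
        interior = np.r_[depth[600 : amp_b.start], depth[amp_a.end : -600]]
        assert abs(interior.mean() - 60) <= 0.2 * 60

    def test_zero_error_reads_match_haplotype(self, ref, haps, clean_pairs_a):
        hap = haps[0]
        expected = list(ref.sequence)
        for v in hap.all_variants:
            if v.vclass == "SNP":
                expected[v.pos] = v.alt_allele
        for pair in clean_pairs_a[:200]:
            for mate in pair.mates:
                rpos, qpos = mate.ref_start, 0
                for op, n in mate.cigar:
                    if op == "M":
                        for k in range(n):
                            pos = rpos + k
                            if not any(v.pos == pos for v in hap.all_variants):
                                assert mate.seq[qpos + k] == expected[pos]
                        rpos += n
                        qpos += n
                    elif op == "D":
                        rpos += n
                    else:
                        qpos += n

    def test_read_lengths_and_pairing(self, clean_pairs_a):
        for pair in clean_pairs_a[:100]:
            assert pair.r1.query_length == 250
            assert pair.r2.query_length == 250
            assert pair.r1.pair_id == pair.r2.pair_id
            assert {pair.r1.strand, pair.r2.strand} == {"+", "-"}

    def test_fragments_stay_inside_amplicons(self, ref, clean_pairs_a):
        amp_a, amp_b = ref.amplicons
        for pair in clean_pairs_a:
            lo = min(m.ref_start for m in pair.mates)
            hi = max(m.ref_end for m in pair.mates)
            assert (amp_a.start <= lo and hi <= amp_a.end) or (
                amp_b.start <= lo and hi <= amp_b.end
            )

    def test_depth_zero_gives_no_reads(self, ref, haps):
        assert simulate_short_reads(ref, haps[0], 0, seed=1) == []

    def test_fragment_shorter_than_read_raises(self, ref, haps):
        with pytest.raises(ConfigurationError):
            simulate_short_reads(ref, haps[0], 10, read_len=250, frag_mean=200)

    def test_noisy_reads_are_cigar_consistent(self, ref, haps):
        pairs = simulate_short_reads(ref, haps[0], 20, seed=5)
        validate_reads(
            [m for p in pairs for m in p.mates], len(ref)
        )

    def test_deterministic_given_seed(self, ref, haps):
        a = simulate_short_reads(ref, haps[0], 10, seed=42)
        b = simulate_short_reads(ref, haps[0], 10, seed=42)
        assert [(p.r1.seq, tuple(p.r1.cigar)) for p in a] == [
            (p.r1.seq, tuple(p.r1.cigar)) for p in b
        ]


class TestLongReads:
    def test_zero_error_full_molecules_span_their_amplicon(self, ref, haps):
        reads = simulate_long_reads(
            ref, haps[0], 20, profile=ErrorProfile.zero(),
            truncated_fraction=0.0, seed=2,
        )
        amp_lengths = {a.length for a in ref.amplicons}
        assert reads
        # contributor A carries one private insertion (+1 query base)
        assert {r.reference_span for r in reads} <= amp_lengths
        for r in reads:
            assert r.query_length >= r.reference_span

    def test_truncated_molecules_are_forward_primer_anchored(self, ref, haps):
        reads = simulate_long_reads(
            ref, haps[0], 20, profile=ErrorProfile.zero(),
            truncated_fraction=1.0, seed=2,
        )
        starts = {a.start for a in ref.amplicons}
        for r in reads:
            assert r.strand == "+"
            assert r.ref_start in starts
            assert 500 <= r.reference_span <= 4000

    def test_bad_truncated_fraction_raises(self, ref, haps):
        with pytest.raises(ConfigurationError):
            simulate_long_reads(ref, haps[0], 10, truncated_fraction=1.5)

    def test_noisy_long_reads_are_cigar_consistent(self, ref, haps):
        reads = simulate_long_reads(ref, haps[0], 10, seed=6)
        validate_reads(reads, len(ref))

    def test_homopolymer_deletion_excess(self, ref, haps):
        """Monte-Carlo: with a 0.5 homopolymer deletion boost, deletion rate
        inside annotated runs far exceeds the background rate outside.

        Every read traverses all runs of its amplicon, so ~800 full-length
        molecules give well over 1,000 run traversals."""
        profile = ErrorProfile(deletion=0.05, homopolymer_extra_deletion=0.5)
        reads = simulate_long_reads(
            ref, haps[1], 400, profile=profile, truncated_fraction=0.0, seed=8
        )
        assert len(reads) >= 600
        pile = build_pileup(reads, ref)
        depths = pile.depths.astype(float)
        mask = ref.homopolymer_mask
        inside = pile.deletion_counts[mask].sum() / depths[mask].sum()
        outside = pile.deletion_counts[~mask].sum() / depths[~mask].sum()
        assert outside == pytest.approx(0.05, rel=0.15)
        assert inside == pytest.approx(0.55, rel=0.15)
        assert inside > 3 * outside


class TestMixture:
    def test_half_vaf_at_private_full_vaf_at_shared(
        self, small_ref, small_haps, deep_clean_mixture_small
    ):
        pile = build_pileup(deep_clean_mixture_small["SHORT"], small_ref)
        for hap in small_haps:
            for v in hap.private_variants:
                if v.vclass != "SNP":
                    continue
                assert vaf(pile[v.pos], v.alt_allele) == pytest.approx(0.5, abs=0.03)
        for v in small_haps[0].shared_variants:
            assert vaf(pile[v.pos], v.alt_allele) == pytest.approx(1.0, abs=0.01)

    def test_unbalanced_ratio_tracks_molecule_share(self, ref, haps):
        mix = simulate_mixture(
            ref, haps[0], haps[1], (0.7, 0.3),
            short_depth=300, long_depth=0,
            short_profile=ErrorProfile.zero(), long_profile=ErrorProfile.zero(),
            seed=4,
        )
        pile = build_pileup(mix["SHORT"], ref)
        for hap, share in ((haps[0], 0.7), (haps[1], 0.3)):
            for v in hap.private_variants:
                if v.vclass != "SNP":
                    continue
                col = pile[v.pos]
                # 4-sigma binomial envelope at the realised depth
                sigma = (share * (1 - share) / col.depth) ** 0.5
                assert vaf(col, v.alt_allele) == pytest.approx(
                    share, abs=max(4 * sigma, 0.02)
                )

    def test_degenerate_ratio_is_single_source(self, ref, haps):
        mix = simulate_mixture(
            ref, haps[0], haps[1], (1.0, 0.0), short_depth=50, long_depth=20,
            seed=4,
        )
        labels = {p.contributor for p in mix["SHORT"]}
        labels |= {r.contributor for r in mix["LONG"]}
        assert labels == {haps[0].contributor_id}

    def test_bad_ratio_raises(self, ref, haps):
        with pytest.raises(ConfigurationError):
            simulate_mixture(ref, haps[0], haps[1], (0.6, 0.6), seed=1)

    def test_truth_labels_retained(self, clean_mixture):
        labels = {p.contributor for p in clean_mixture["SHORT"]}
        assert labels == {"005", "047"}


def test_coverage_conservation(ref, clean_pairs_a):
    """Sum of per-base depth equals the sum of aligned reference spans."""
    from mitomix.reconstruct import coverage_track

    depth = coverage_track(clean_pairs_a, ref)
    spans = sum(m.reference_span for p in clean_pairs_a for m in p.mates)
    assert depth.sum() == spans
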