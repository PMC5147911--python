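"""Pileup construction, VAF arithmetic, threshold calling and variant
normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomix import build_pileup, call_snps, left_align_and_decompose, vaf
from mitomix.pileup import (
    Pileup,
    PileupColumn,
    ReferenceMismatchError,
    UndefinedVAFError,
)
from mitomix.reads import MalformedAlignmentError
from mitomix.simdata import ReferenceGenome, Variant

from conftest import haplotype_base


def make_column(pos=0, deletions=0, insertions=None, **base_counts):
    counts = {b: base_counts.get(b, 0) for b in "ACGT"}
    return PileupColumn(pos, counts, deletions, insertions or {})


class TestBuildPileup:
    def test_single_read_simple_match(self, ref, mk_read):
        read = mk_read(5, "10M", ref.sequence[5:15])
        pile = build_pileup([read], ref)
        depths = pile.depths
        assert (depths[5:15] == 1).all()
        assert depths[:5].sum() == 0 and depths[15:].sum() == 0

    def test_deletion_counts_toward_depth(self, ref, mk_read):
        seq = ref.sequence[0:5] + ref.sequence[7:12]
        read = mk_read(0, "5M2D5M", seq)
        pile = build_pileup([read], ref)
        assert pile[5].deletion_count == 1
        assert pile[6].deletion_count == 1
        assert pile[5].depth == 1  # deletion-spanning read still covers
        for pos in list(range(5)) + list(range(7, 12)):
            assert pile[pos].counts[ref.sequence[pos]] == 1

    def test_insertion_anchored_at_preceding_position(self, ref, mk_read):
        seq = ref.sequence[10:15] + "GG" + ref.sequence[15:20]
        read = mk_read(10, "5M2I5M", seq)
        pile = build_pileup([read], ref)
        assert pile[14].insertion_events == {"GG": 1}
        assert pile.depths.sum() == 10  # I consumes no reference

    def test_soft_clips_contribute_nothing(self, ref, mk_read):
        read = mk_read(30, "3S5M2S", "TTT" + ref.sequence[30:35] + "GG")
        pile = build_pileup([read], ref)
        assert pile.depths.sum() == 5

    def test_secondary_and_unmapped_excluded(self, ref, mk_read):
        r1 = mk_read(0, "5M", ref.sequence[:5], is_secondary=True)
        r2 = mk_read(0, "5M", ref.sequence[:5], is_mapped=False)
        assert build_pileup([r1, r2], ref).depths.sum() == 0

    def test_read_past_reference_end_raises(self, ref, mk_read):
        read = mk_read(len(ref) - 3, "10M", "ACGTACGTAC")
        with pytest.raises(MalformedAlignmentError):
            build_pileup([read], ref)

    def test_zero_error_majority_matches_haplotype(self, ref, haps, clean_pairs_a):
        pile = build_pileup(clean_pairs_a, ref)
        depths = pile.depths
        covered = np.flatnonzero(depths > 0)
        majority = np.argmax(pile.base_counts, axis=1)
        for pos in covered[:: max(1, len(covered) // 500)]:
            expected = haplotype_base(ref, haps[0], int(pos))
            assert "ACGT"[majority[pos]] == expected

    def test_depth_equals_brute_force_cover_count(self, ref, haps):
        """Column conservation against a brute-force read-span oracle."""
        from mitomix.simdata import simulate_long_reads

        reads = simulate_long_reads(ref, haps[0], 2, seed=17)
        pile = build_pileup(reads, ref)
        depths = pile.depths
        rng = np.random.default_rng(0)
        for pos in rng.integers(0, len(ref), size=200):
            brute = sum(r.ref_start <= pos < r.ref_end for r in reads)
            assert depths[pos] == brute


class TestVAF:
    def test_minion_mixture_locus(self):
        # 146 A / 180 G / 14 other reads: A at 43%
        col = make_column(A=146, G=180, C=10, T=4)
        assert col.depth == 340
        assert vaf(col, "A") == pytest.approx(0.4294, abs=5e-4)
        assert round(100 * vaf(col, "A")) == 43

    def test_low_frequency_alternate(self):
        # 951 T / 178 C / 6 other: the 0.16 alternate-C fraction
        col = make_column(T=951, C=178, A=6)
        assert vaf(col, "C") == pytest.approx(0.157, abs=5e-4)
        assert round(vaf(col, "C"), 2) == 0.16

    def test_absent_allele_is_zero(self):
        col = make_column(T=50)
        assert vaf(col, "A") == 0.0

    def test_deletions_inflate_denominator(self):
        col = make_column(A=50, deletions=50)
        assert vaf(col, "A") == 0.5

    def test_zero_depth_raises(self):
        with pytest.raises(UndefinedVAFError):
            vaf(make_column(), "A")


class TestCallSNPs:
    @pytest.fixture()
    def toy(self):
        ref = ReferenceGenome("toy", "ACGT" * 25, homopolymers=[])
        pile = Pileup(100)
        pile.base_counts[:, :] = 0
        for pos in range(100):
            pile.base_counts[pos, "ACGT".index(ref.sequence[pos])] = 100
        return ref, pile

    def test_threshold_semantics(self, toy):
        ref, pile = toy
        # alt fraction 0.43 at position 10 (ref G)
        pile.base_counts[10] = 0
        pile.base_counts[10, 0] = 43  # A
        pile.base_counts[10, 2] = 57  # G (ref)
        assert (10, "A") not in call_snps(pile, ref, 0.45, min_depth=20)
        assert (10, "A") in call_snps(pile, ref, 0.40, min_depth=20)

    def test_deletion_signal_never_called(self, toy):
        ref, pile = toy
        pile.base_counts[20] = 0
        pile.base_counts[20, "ACGT".index(ref.sequence[20])] = 10
        pile.deletion_counts[20] = 90
        calls = call_snps(pile, ref, 0.5, min_depth=20)
        assert not any(pos == 20 for pos, _ in calls.sites)

    def test_insertion_signal_never_called(self, toy):
        ref, pile = toy
        pile.insertions[30] = {"TT": 95}
        assert not any(pos == 30 for pos, _ in call_snps(pile, ref, 0.5).sites)

    def test_min_depth_floor(self, toy):
        ref, pile = toy
        pile.base_counts[40] = 0
        pile.base_counts[40, 1] = 15  # depth 15 < 20, pure alt C (ref is A)
        assert (40, "C") not in call_snps(pile, ref, 0.9, min_depth=20)
        assert (40, "C") in call_snps(pile, ref, 0.9, min_depth=10)

    def test_single_source_keeps_one_alt_mixture_two(self, toy):
        ref, pile = toy
        pos = 50  # ref C at 50? sequence ACGT repeating: pos 50 % 4 == 2 -> G
        pile.base_counts[pos] = 0
        pile.base_counts[pos, 0] = 55  # A
        pile.base_counts[pos, 3] = 45  # T
        single = call_snps(pile, ref, 0.3, min_depth=20, ploidy_mode="single_source")
        mixture = call_snps(pile, ref, 0.3, min_depth=20, ploidy_mode="mixture")
        assert {s for s in single.sites if s[0] == pos} == {(pos, "A")}
        assert {s for s in mixture.sites if s[0] == pos} == {(pos, "A"), (pos, "T")}

    def test_threshold_nesting_is_monotone(self, ref, haps):
        from mitomix.simdata import simulate_short_reads

        pairs = simulate_short_reads(ref, haps[0], 40, seed=21)
        pile = build_pileup(pairs, ref)
        previous = None
        for t in (0.05, 0.25, 0.45, 0.65, 0.85):
            calls = call_snps(pile, ref, t).sites
            if previous is not None:
                assert calls <= previous
            previous = calls

    def test_zero_error_recovery_at_high_threshold(self, ref, haps, clean_pairs_a):
        pile = build_pileup(clean_pairs_a, ref)
        calls = call_snps(pile, ref, 0.9, min_depth=20)
        assert calls.sites == haps[0].snp_sites()

    def test_empty_pileup_returns_empty_set(self, toy):
        ref, _ = toy
        assert len(call_snps(Pileup(100), ref, 0.5)) == 0


class TestNormalization:
    @pytest.fixture()
    def toy_ref(self):
        #            0123456789012345
        sequence = "GATCACCCCATTGACA" * 10
        return ReferenceGenome("toy", sequence, homopolymers=[])

    def test_block_substitution_decomposes(self, toy_ref):
        # AC -> GT at positions 4-5
        out = left_align_and_decompose([Variant(4, "AC", "GT")], toy_ref)
        assert out == [Variant(4, "A", "G"), Variant(5, "C", "T")]

    def test_multiallelic_splits(self, toy_ref):
        out = left_align_and_decompose([Variant(1, "A", "C,G")], toy_ref)
        assert out == [Variant(1, "A", "C"), Variant(1, "A", "G")]

    def test_insertion_shifts_to_run_start(self, toy_ref):
        # C inserted after the last C of the CCCC run (positions 4-8: ACCCC)
        out = left_align_and_decompose([Variant(8, "C", "CC")], toy_ref)
        assert out == [Variant(4, "A", "AC")]

    def test_deletion_shifts_left(self, toy_ref):
        out = left_align_and_decompose([Variant(7, "CC", "C")], toy_ref)
        assert out == [Variant(4, "AC", "A")]

    def test_idempotent(self, toy_ref):
        variants = [Variant(8, "C", "CC"), Variant(4, "AC", "GT")]
        once = left_align_and_decompose(variants, toy_ref)
        twice = left_align_and_decompose(once, toy_ref)
        assert once == twice

    def test_ref_mismatch_raises(self, toy_ref):
        with pytest.raises(ReferenceMismatchError):
            left_align_and_decompose([Variant(0, "T", "A")], toy_ref)

    @given(
        run_pos=st.integers(min_value=1, max_value=6),
        data=st.data(),
    )
    @settings(max_examples=30, deadline=None)
    def test_insertion_in_run_always_lands_at_run_start(self, run_pos, data):
        """Property: inserting the run base anywhere inside a homopolymer run
        normalizes to the run's leftmost anchor."""
        seq = "GT" + "A" * 8 + "CG" * 20
        ref = ReferenceGenome("toy", seq, homopolymers=[])
        pos = 1 + run_pos  # anchor inside the A-run (run occupies 2..9)
        out = left_align_and_decompose([Variant(pos, seq[pos], seq[pos] + "A")], ref)
        assert out == [Variant(1, "T", "TA")]
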