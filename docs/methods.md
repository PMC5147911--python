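# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitomix`, and what the synthetic study design does and does not
establish about real data.

## Synthetic study design

The simulator (`mitomix.simdata`) emulates a dual-platform sequencing study
of a two-person mitochondrial mixture.  Its defaults define the conditions
under which every downstream claim is tested:

| parameter | default | rationale |
|---|---|---|
| genome length | 16,569 bp | human mitochondrial genome size |
| amplicons | 8,600 / 8,300 bp, overlapping | two long-PCR products tiling the circle |
| shared SNPs | 31 | same-haplogroup backbone of the two contributors |
| private variants | 6 SNPs + 1 insertion per contributor | the only signal separating contributors |
| mixture ratio | 1:1 | the hardest balanced case |
| short platform | 1000×, 2×250 bp pairs, frag 450±50; sub 2·10⁻³, indel 10⁻⁴ each | order-of-magnitude realistic for a low-error sequencing-by-synthesis chemistry |
| long platform | 300×, full-amplicon molecules; sub 0.05, ins 0.04, del 0.05 | order-of-magnitude realistic for a nanopore-class chemistry |
| homopolymer extra deletion | +0.15 per base in runs ≥ 5 | the dominant long-read failure mode |
| truncated long-read fraction | 0.3, forward-strand, 500–4000 bp from a primer | failed extensions / early termination products |
| base qualities | constant 35 (short) / 10 (long) | long-read scores are not phred-calibrated, so the caller uses a depth floor instead of base quality |
| default seed | 1001 | reproducibility anchor |

No published per-base error rates exist for the emulated platforms at this
study's vintage; the rates above are order-of-magnitude choices fixed before
any acceptance measurement and not tuned thereafter.

**Circular origin handling.**  In the physical design the second amplicon
spans the circular origin, and the two amplicons overlap at *two* arcs of
the circle.  The simulator generates the genome directly in *rotated*
coordinates — amplicon A at `[0, 8600)`, amplicon B at `[8269, 16569)` —
which makes both amplicons contiguous and leaves one explicit interior
overlap (~331 bp); the second physical overlap is collapsed to the rotation
cut at the origin (a zero-width junction).  A true two-overlap linear layout
is impossible (one amplicon would have to wrap), and this choice preserves
the property that matters downstream: no read ever spans the sequence end,
so no split alignments are needed.  The rotation amount (0 by construction)
is recorded in the run manifest.

**Alignment is simulated, not performed.**  Reads are emitted at their true
positions with CIGARs that encode the injected variants and errors (`M`
rather than `=`/`X`, so the deconvolution rules over "match (M)" operations
apply literally).  This removes aligner artifacts from every experiment; see
*Limitations*.

**Variant placement.**  Private variants are confined to the phasing
extraction intervals `[1000, 8000)` and `[10000, 15000)` (where they are
informative for both phasing and deconvolution), keep 25 bp mutual spacing
(so insertion ±10 bp windows never overlap another panel site), and avoid
primer intervals and a 600 bp margin at the rotation cut where short-read
coverage ramps down.  When the genome carries planted homopolymer runs, one
private SNP of the first contributor is placed mid-run to exercise the
long-read deletion error mode.

## Calling model

The caller is a transparent frequency thresholder, not a genotyper:

- VAF of allele *b* at a column = `count(b) / depth`, with depth counting
  every covering read — including deletion-spanning reads and third alleles.
  This convention was checked against the published per-locus count tables
  it mirrors (e.g. 146/(146+180+14) → 43%).
- A site yields a SNP call when depth ≥ `min_depth` (default 20) and a
  non-reference base has VAF ≥ *t*.  The depth floor replaces an external
  caller's `QUAL > 20` filter, which is not meaningful when one platform's
  quality scores are uncalibrated.
- Ploidy is expressed through alternate retention: `single_source` mode
  keeps at most the highest-VAF alternate per position, `mixture` mode up to
  two.  Insertion/deletion evidence never becomes a SNP call.
- Normalization (`left_align_and_decompose`) splits multi-allelic records
  and block substitutions into primitive biallelic calls and left-aligns
  indels through repeated sequence; it is idempotent and validates the
  stated reference allele.

## Concordance

Sites are matched by (position, alternate allele); a right-position,
wrong-allele call counts as one FP *and* one FN — stricter than matching by
position alone, and stated because published definitions leave the allele
case open.  Metrics with zero denominators are reported as `null`, never 0;
F1 is 0 when TP = 0 with FP+FN > 0.  Grid argmax reports *all* tied cells in
row-major order, since plateaus of equal F1 across threshold windows are
expected (call sets only change when a threshold crosses an observed VAF).
Reported metrics round half-even at 3 decimals.

## Phasing

Given private heterozygous sites (from the combined truth set, not
re-estimated), each spanning read's allele vector is compared with the two
candidate haplotype vectors; the read joins the pool it matches at strictly
more covered sites, ties and zero-information reads stay unassigned.  A
refinement loop recomputes each pool's per-site majority consensus and
re-assigns until stable (≤ 10 iterations; a consensus that ties at a site
falls back to the seed allele, which keeps label-swap symmetry exact).
Sites under a deletion or insertion in a read are *missing*, not
mismatches.  The >8000-base rule is applied to query length (not aligned
span): the intent is to keep only fully extended amplicon molecules, and
query length is the quantity that a heavily deletion-eroded read fails.

## Deconvolution

Pair-level, both mates always together.  SNP evidence requires the covering
CIGAR op to be `M` and the observed base to equal one contributor's allele;
mates that disagree cancel.  Insertion evidence requires the pair to cover
both `pos-10` and `pos+10` (either mate may contribute a flank); an `I` op
anchored at the site routes to the carrier, otherwise to the other
contributor.  An insertion is "anchored at p" when it sits between
reference positions p and p+1 — the same convention the pileup uses.
Verdicts across all covered panel sites aggregate by majority; ties go to
the shared pool (conservative: ambiguous pairs never contaminate a private
pool).  The panel's SNPs come from the combined truth call sets; its
insertions are detected from the single-source short-read pileups (anchors
where insertion events reach half of depth in exactly one contributor).

## Reconstruction and assembly statistics

Reference-guided consensus replaces de-novo hybrid assembly: the merged
phased-long + deconvolved-short pool is re-piled and every signal reaching
VAF ≥ 0.75 (SNP, insertion, single-base deletion) is applied to the
reference; uncovered positions are N-filled and reported as gaps.  The
claim this tests — the reconstructed call set is 100% concordant with the
contributor's variants at VAF 0.75 — is a variant-set property and does not
require an assembler.  Nx is the length of the smallest contig in the
minimal largest-first prefix reaching x% of total contig length; NGAx uses
x% of the *genome* length and alignment-broken block lengths, and is `null`
where the blocks cover less than x% of the genome.  Blocks are taken as
given (whole contigs when the consensus is gapless); no misassembly
detection is performed, and ambiguous placements are expected to be removed
by the caller before NGAx.

## Numerical conventions

- Coordinates are 0-based half-open internally; all files and reports print
  1-based positions ("np").
- Threshold grids are computed as `lo + i*step` rounded to 10 decimals, so
  float accumulation never drops the final threshold (19 thresholds for
  both 0.05–0.95/0.05 and 0.17–0.53/0.02).
- VAF comparisons use plain `>=` — thresholds are interpreted exactly.
- Per-stage seeds derive from the global seed via a seed sequence; identical
  configuration + seed reproduces byte-identical SAM/TSV/JSON outputs
  (verified by manifest digests).
- Whole-percent figures round half-even; site-report percentages may sum to
  100 ± 1 under rounding.

## Problem sizes

The default pipeline (two single sources + mixture at 1000×/300×, 19×19 and
1×19 grids, phasing, deconvolution, reconstruction) processes ≈ 100k read
pairs and ≈ 2k long reads in about half a minute on one CPU; tests use
reduced depths (40–400×) except the end-to-end acceptance properties, which
run once at full depth.

## Limitations

- The error model is i.i.d. per base apart from the homopolymer deletion
  boost; real long-read error is sequence-context dependent well beyond
  homopolymers, and real short-read error is quality- and cycle-dependent.
  Passing recovery tests here shows the *pipeline logic* is correct under
  calibrated noise, not that real data of these depths would separate as
  cleanly.
- No aligner is involved, so alignment artifacts — reference-bias, split
  alignments at the circular origin, ambiguous placement in repetitive
  control-region loci (the classic length-heteroplasmy sites) — are absent.
  The SNP-only filter is the only defence against such artifacts that this
  package implements.
- Phasing is strictly two-haplotype; mixtures of k > 2 contributors, or
  ratios far from 1:1 at low depth, are out of scope.
- The private-variant panel contains SNPs and insertions only; deletion
  privates are not supported by the routing rules.
- Base-quality information is carried but unused by the caller (by design);
  quality-aware counting could change behaviour on real data.
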