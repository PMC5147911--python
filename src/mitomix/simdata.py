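"""Synthetic dual-platform mitochondrial read simulator.

Emulates the study design this package analyses: a ~16.6 kb circular genome
enriched as two overlapping long-PCR amplicons (~8.3 kb and ~8.6 kb), two
contributors of the same haplogroup that share a SNP backbone and differ by a
small panel of private SNPs and insertions, a deep low-error short-read
platform and a shallower high-error long-read platform whose dominant failure
mode is deletion inside homopolymer runs of five or more identical bases.

Reads are emitted pre-aligned at their true positions with CIGAR strings that
encode the injected variants and errors, so no external aligner is involved;
downstream stages consume SAM-level alignments exactly as they would from a
mapping pipeline.  The genome is generated directly in *rotated* coordinates:
the circular origin is placed at the cut between the two amplicons so that
both are contiguous on the linear sequence (the rotation amount is recorded
on the genome and in the run manifest).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional, Sequence

import numpy as np

from .reads import AlignedRead, Cigar, ReadPair, slice_alignment

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate(BASES)}

# Amplicon sizes as fractions of the genome (8,600 and 8,300 of 16,569 bp)
_AMP_FRAC_A = 8600 / 16569
_AMP_FRAC_B = 8300 / 16569
PRIMER_LEN = 30

DEFAULT_SEED = 1001


class ConfigurationError(ValueError):
    """Simulation parameters are inconsistent."""


class SizingError(ValueError):
    """Genome too small to host the requested amplicons or homopolymer runs."""


class PlacementError(RuntimeError):
    """Could not place variants without positional collisions."""


def _decode(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode()


def encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for b, i in _CODE.items():
        codes[codes == ord(b)] = i
    return codes


@dataclass(frozen=True)
class AmpliconDef:
    """A long-PCR amplicon in rotated (linear) coordinates, 0-based half-open."""

    name: str
    start: int
    end: int
    primer_intervals: tuple[tuple[int, int], tuple[int, int]]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class Variant:
    """A sequence variant in 0-based reference coordinates.

    SNP: single-base substitution.  INS: ``ref_allele`` is the anchor base and
    ``alt_allele`` is anchor + inserted sequence (the insertion sits between
    ``pos`` and ``pos + 1``).  DEL: ``alt_allele`` is the retained anchor base.
    """

    pos: int
    ref_allele: str
    alt_allele: str

    @property
    def vclass(self) -> str:
        if len(self.ref_allele) == 1 == len(self.alt_allele):
            return "SNP"
        if len(self.ref_allele) == 1 < len(self.alt_allele):
            return "INS"
        if len(self.alt_allele) == 1 < len(self.ref_allele):
            return "DEL"
        return "MNP"


@dataclass
class ReferenceGenome:
    """Circular reference with annotated homopolymer runs and amplicons."""

    name: str
    sequence: str
    circular: bool = True
    homopolymers: list[tuple[int, int, str]] = field(default_factory=list)
    amplicons: list[AmpliconDef] = field(default_factory=list)
    rotation: int = 0

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(BASES):
            raise ValueError("sequence must be non-empty A/C/G/T")
        for start, run, base in self.homopolymers:
            if not (0 <= start and start + run <= len(self)):
                raise ValueError(f"homopolymer ({start},{run}) outside genome")
            if self.sequence[start : start + run] != base * run:
                raise ValueError(f"annotated run at {start} does not match sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    @cached_property
    def homopolymer_mask(self) -> np.ndarray:
        """Per-base mask of annotated runs (where the long-read deletion
        excess applies; annotation is restricted to runs of length >= 5)."""
        mask = np.zeros(len(self), dtype=bool)
        for start, run, _ in self.homopolymers:
            if run >= 5:
                mask[start : start + run] = True
        return mask


@dataclass
class HaplotypeSpec:
    """Ground-truth variant profile of one mixture contributor."""

    contributor_id: str
    shared_variants: list[Variant]
    private_variants: list[Variant]

    def __post_init__(self) -> None:
        pos_shared = {v.pos for v in self.shared_variants}
        pos_private = {v.pos for v in self.private_variants}
        if pos_shared & pos_private:
            raise ValueError("shared and private variant positions overlap")
        if len(pos_shared) != len(self.shared_variants) or len(pos_private) != len(
            self.private_variants
        ):
            raise ValueError("duplicate variant positions within one haplotype")

    @property
    def all_variants(self) -> list[Variant]:
        return sorted(self.shared_variants + self.private_variants)

    def snp_sites(self) -> set[tuple[int, str]]:
        """(pos, alt) pairs of this haplotype's SNPs (shared + private)."""
        return {
            (v.pos, v.alt_allele) for v in self.all_variants if v.vclass == "SNP"
        }


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates of a sequencing platform.

    ``homopolymer_extra_deletion`` is an additional per-base deletion
    probability applied only inside annotated homopolymer runs (length >= 5),
    modelling the long-read chemistry's run-length blindness.
    """

    substitution: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0
    homopolymer_extra_deletion: float = 0.0

    def __post_init__(self) -> None:
        for rate in (
            self.substitution,
            self.insertion,
            self.deletion,
            self.homopolymer_extra_deletion,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"error rate {rate} outside [0, 1]")

    @classmethod
    def zero(cls) -> "ErrorProfile":
        return cls()

    @classmethod
    def short_default(cls) -> "ErrorProfile":
        return cls(substitution=0.002, insertion=0.0001, deletion=0.0001)

    @classmethod
    def long_default(cls) -> "ErrorProfile":
        return cls(
            substitution=0.05,
            insertion=0.04,
            deletion=0.05,
            homopolymer_extra_deletion=0.15,
        )


SHORT_QUAL = 35
LONG_QUAL = 10


# ---------------------------------------------------------------------------
# reference + haplotype generation


def generate_reference(
    length: int = 16569,
    n_homopolymers: int = 3,
    min_run: int = 6,
    seed: int = DEFAULT_SEED,
    name: str = "chrM_synth",
) -> ReferenceGenome:
    """Generate a circular genome with planted homopolymer runs and two
    overlapping amplicons covering it.

    The two amplicons are sized proportionally to 8.6/8.3 kb on a 16,569 bp
    genome and laid out contiguously in rotated coordinates:
    ``A = [0, lenA)`` and ``B = [length - lenB, length)`` with an interior
    overlap; the second physical overlap of the circular design is collapsed
    to the rotation cut at the origin.
    """
    if length < 1000:
        raise SizingError(f"genome length {length} < 1000 cannot host amplicons")
    len_a = int(round(length * _AMP_FRAC_A))
    len_b = int(round(length * _AMP_FRAC_B))
    if len_a + len_b <= length:
        raise SizingError("amplicons do not overlap at this genome size")
    if n_homopolymers * (min_run + 4) > length // 4:
        raise SizingError("too many homopolymer runs for this genome size")
    if min_run < 5:
        raise SizingError("min_run must be >= 5 (annotation threshold)")

    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)

    runs: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for _ in range(n_homopolymers):
        run_len = int(min_run + rng.integers(0, 3))
        for _attempt in range(200):
            start = int(rng.integers(50, length - run_len - 50))
            if all(start + run_len + 2 <= s or start >= e + 2 for s, e in occupied):
                break
        else:
            raise SizingError("could not place homopolymer runs without overlap")
        base_code = int(rng.integers(0, 4))
        codes[start : start + run_len] = base_code
        # break the run cleanly at both flanks
        for flank in (start - 1, start + run_len):
            if codes[flank] == base_code:
                codes[flank] = (base_code + 1 + rng.integers(0, 3)) % 4
        occupied.append((start, start + run_len))
        runs.append((start, run_len, BASES[base_code]))

    amp_a = AmpliconDef(
        "amp_a", 0, len_a, ((0, PRIMER_LEN), (len_a - PRIMER_LEN, len_a))
    )
    amp_b = AmpliconDef(
        "amp_b",
        length - len_b,
        length,
        ((length - len_b, length - len_b + PRIMER_LEN), (length - PRIMER_LEN, length)),
    )
    return ReferenceGenome(
        name=name,
        sequence=_decode(codes),
        homopolymers=sorted(runs),
        amplicons=[amp_a, amp_b],
        rotation=0,
    )


def generate_haplotypes(
    ref: ReferenceGenome,
    n_shared: int = 31,
    n_private_snps_each: int = 6,
    n_private_ins_each: int = 1,
    seed: int = DEFAULT_SEED,
    contributor_ids: tuple[str, str] = ("005", "047"),
    edge_margin: int = 600,
    min_spacing: int = 25,
    private_regions: Optional[Sequence[tuple[int, int]]] = None,
) -> tuple[HaplotypeSpec, HaplotypeSpec]:
    """Draw two same-haplogroup haplotypes: an identical shared SNP backbone
    plus per-contributor private SNPs and insertions.

    When the genome carries planted homopolymer runs and the first contributor
    has at least one private SNP, one of its private SNPs is placed inside a
    run to exercise the homopolymer error mode.  Private positions avoid
    primer intervals and an ``edge_margin`` around the rotation cut (where
    short-read coverage ramps down); when ``private_regions`` is given,
    private variants are confined to those intervals (the amplicon interiors
    where they are informative for phasing and deconvolution).
    """
    rng = np.random.default_rng(seed)
    length = len(ref)
    forbidden = np.zeros(length, dtype=bool)
    forbidden[:edge_margin] = True
    forbidden[length - edge_margin :] = True
    for amp in ref.amplicons:
        for lo, hi in amp.primer_intervals:
            forbidden[max(0, lo - min_spacing) : min(length, hi + min_spacing)] = True

    n_total = n_shared + 2 * (n_private_snps_each + n_private_ins_each)
    chosen: list[int] = []

    def pick(candidates: np.ndarray) -> int:
        for _ in range(500):
            pos = int(rng.choice(candidates))
            if not forbidden[pos] and all(abs(pos - c) >= min_spacing for c in chosen):
                chosen.append(pos)
                return pos
        raise PlacementError(f"could not place {n_total} variants without collision")

    all_positions = np.arange(length)
    if private_regions:
        private_positions = np.concatenate(
            [np.arange(max(0, lo), min(length, hi)) for lo, hi in private_regions]
        )
    else:
        private_positions = all_positions

    def make_snp(pos: int) -> Variant:
        ref_base = ref.sequence[pos]
        alt = BASES[(_CODE[ref_base] + 1 + int(rng.integers(0, 3))) % 4]
        return Variant(pos, ref_base, alt)

    def make_ins(pos: int) -> Variant:
        anchor = ref.sequence[pos]
        inserted = BASES[int(rng.integers(0, 4))]
        return Variant(pos, anchor, anchor + inserted)

    shared = sorted(make_snp(pick(all_positions)) for _ in range(n_shared))

    privates: list[list[Variant]] = []
    for k, _cid in enumerate(contributor_ids):
        vs: list[Variant] = []
        n_snps = n_private_snps_each
        if k == 0 and n_snps >= 1 and ref.homopolymers:
            run_positions = np.array(
                [s + ln // 2 for s, ln, _ in ref.homopolymers if ln >= 5]
            )
            usable = run_positions[
                ~forbidden[run_positions] & np.isin(run_positions, private_positions)
            ]
            if usable.size:
                vs.append(make_snp(pick(usable)))
                n_snps -= 1
        vs.extend(make_snp(pick(private_positions)) for _ in range(n_snps))
        vs.extend(make_ins(pick(private_positions)) for _ in range(n_private_ins_each))
        privates.append(sorted(vs))

    hap_a = HaplotypeSpec(contributor_ids[0], list(shared), privates[0])
    hap_b = HaplotypeSpec(contributor_ids[1], list(shared), privates[1])
    return hap_a, hap_b


# ---------------------------------------------------------------------------
# molecule-level error walk


class _HapArrays:
    """Haplotype variants pre-compiled to genome-wide lookup arrays."""

    def __init__(self, ref: ReferenceGenome, hap: HaplotypeSpec) -> None:
        self.snp_code = np.full(len(ref), -1, dtype=np.int8)
        self.ins: dict[int, np.ndarray] = {}
        self.deleted = np.zeros(len(ref), dtype=bool)
        for v in hap.all_variants:
            if v.vclass == "SNP":
                self.snp_code[v.pos] = _CODE[v.alt_allele]
            elif v.vclass == "INS":
                self.ins[v.pos] = encode(v.alt_allele[1:])
            elif v.vclass == "DEL":
                self.deleted[v.pos + 1 : v.pos + len(v.ref_allele)] = True
        self.ins_anchor = np.zeros(len(ref), dtype=bool)
        for p in self.ins:
            self.ins_anchor[p] = True


def _simulate_molecule(
    ref: ReferenceGenome,
    hap_arrays: _HapArrays,
    start: int,
    end: int,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[str, Cigar, int]:
    """Simulate one molecule over reference window ``[start, end)``.

    Applies haplotype variants, then per-base sequencing errors; returns the
    read sequence (reference orientation), CIGAR and the (possibly trimmed)
    reference start.
    """
    n = end - start
    w = ref.codes[start:end].copy()
    snp = hap_arrays.snp_code[start:end]
    w = np.where(snp >= 0, snp.astype(np.uint8), w)

    if profile.substitution > 0:
        m = rng.random(n) < profile.substitution
        if m.any():
            w[m] = (w[m] + rng.integers(1, 4, size=int(m.sum()))) % 4

    p_del = np.full(n, profile.deletion)
    if profile.homopolymer_extra_deletion > 0:
        p_del += profile.homopolymer_extra_deletion * ref.homopolymer_mask[start:end]
    del_mask = (rng.random(n) < p_del) | hap_arrays.deleted[start:end]

    ins_after: dict[int, np.ndarray] = {}
    if profile.insertion > 0:
        for i in np.flatnonzero(rng.random(n) < profile.insertion):
            ins_after[int(i)] = rng.integers(0, 4, size=1, dtype=np.uint8)
    for i in np.flatnonzero(hap_arrays.ins_anchor[start:end]):
        i = int(i)
        seq = hap_arrays.ins[start + i]
        ins_after[i] = np.concatenate([ins_after.get(i, np.empty(0, np.uint8)), seq])
        del_mask[i] = False  # the anchor base of a true insertion is retained

    # assemble sequence + CIGAR; only exceptional offsets need python-level work
    exceptional = sorted(set(np.flatnonzero(del_mask).tolist()) | set(ins_after))
    parts: list[np.ndarray] = []
    cigar: Cigar = []

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    cursor = 0
    for i in exceptional:
        if i > cursor:
            push("M", i - cursor)
            parts.append(w[cursor:i])
        if del_mask[i]:
            push("D", 1)
        else:
            push("M", 1)
            parts.append(w[i : i + 1])
        if i in ins_after:
            push("I", len(ins_after[i]))
            parts.append(ins_after[i])
        cursor = i + 1
    if cursor < n:
        push("M", n - cursor)
        parts.append(w[cursor:])

    ref_start = start
    while cigar and cigar[0][0] == "D":
        ref_start += cigar.pop(0)[1]
    trim_back = 0
    while cigar and cigar[-1][0] in "DI":
        op, ln = cigar.pop()
        if op == "I":
            trim_back += ln
    seq_codes = np.concatenate(parts) if parts else np.empty(0, np.uint8)
    if trim_back:
        seq_codes = seq_codes[:-trim_back]
    return _decode(seq_codes), cigar, ref_start


# ---------------------------------------------------------------------------
# platform simulators


def simulate_short_reads(
    ref: ReferenceGenome,
    hap: HaplotypeSpec,
    depth: float,
    read_len: int = 250,
    frag_mean: float = 450,
    frag_sd: float = 50,
    profile: Optional[ErrorProfile] = None,
    seed: int = DEFAULT_SEED,
    sample: Optional[str] = None,
) -> list[ReadPair]:
    """Simulate paired-end short reads at the requested mean fold-coverage.

    Fragments are drawn uniformly *within* amplicon intervals (tagmentation of
    an amplicon never yields a molecule spanning an amplicon end), so coverage
    is flat over amplicon interiors, doubled in the overlap, and ramps down
    toward the rotation cut.
    """
    if profile is None:
        profile = ErrorProfile.short_default()
    if frag_mean < read_len:
        raise ConfigurationError(
            f"fragment mean {frag_mean} shorter than read length {read_len}"
        )
    if depth < 0:
        raise ConfigurationError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    arrays = _HapArrays(ref, hap)
    label = f"{sample}.{hap.contributor_id}" if sample else hap.contributor_id
    pairs: list[ReadPair] = []
    counter = itertools.count()
    for amp in ref.amplicons:
        n_pairs = int(round(depth * amp.length / (2 * read_len)))
        if n_pairs == 0:
            continue
        frag_lens = np.clip(
            rng.normal(frag_mean, frag_sd, size=n_pairs), read_len, amp.length
        ).astype(int)
        starts = amp.start + (
            rng.random(n_pairs) * (amp.length - frag_lens + 1)
        ).astype(int)
        fwd_first = rng.random(n_pairs) < 0.5
        for k in range(n_pairs):
            fs, fl = int(starts[k]), int(frag_lens[k])
            seq, cigar, ref_start = _simulate_molecule(
                ref, arrays, fs, fs + fl, profile, rng
            )
            qlen = len(seq)
            if qlen == 0:
                continue
            r1_hi = min(read_len, qlen)
            r2_lo = max(0, qlen - read_len)
            try:
                s1, c1, rs1 = slice_alignment(seq, cigar, ref_start, 0, r1_hi)
                s2, c2, rs2 = slice_alignment(seq, cigar, ref_start, r2_lo, qlen)
            except ValueError:
                continue  # fragment degenerated to no aligned bases
            pid = f"{label}_F{next(counter):06d}"
            strands = ("+", "-") if fwd_first[k] else ("-", "+")
            mk = lambda i, s, c, rs, st: AlignedRead(
                read_id=f"{pid}/{i}",
                platform="SHORT",
                ref_start=rs,
                cigar=c,
                seq=s,
                quals=np.full(len(s), SHORT_QUAL, dtype=np.uint8),
                strand=st,
                contributor=hap.contributor_id,
                pair_id=pid,
                mate=i,
            )
            pairs.append(
                ReadPair(mk(1, s1, c1, rs1, strands[0]), mk(2, s2, c2, rs2, strands[1]))
            )
    return pairs


def simulate_long_reads(
    ref: ReferenceGenome,
    hap: HaplotypeSpec,
    depth: float,
    profile: Optional[ErrorProfile] = None,
    truncated_fraction: float = 0.3,
    seed: int = DEFAULT_SEED,
    sample: Optional[str] = None,
) -> list[AlignedRead]:
    """Simulate single-molecule long reads over the two amplicons.

    A fraction ``1 - truncated_fraction`` of molecules traverse a full
    amplicon (targeting query lengths above 8,000 bases after error
    injection); the rest are forward-strand partial products anchored at the
    amplicon's forward primer with reference spans uniform in [500, 4000] bp,
    reproducing the primer-proximal coverage excess of failed extensions.
    """
    if profile is None:
        profile = ErrorProfile.long_default()
    if not 0.0 <= truncated_fraction <= 1.0:
        raise ConfigurationError("truncated_fraction outside [0, 1]")
    if depth < 0:
        raise ConfigurationError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    arrays = _HapArrays(ref, hap)
    label = f"{sample}.{hap.contributor_id}" if sample else hap.contributor_id
    mean_trunc = (500 + 4000) / 2
    reads: list[AlignedRead] = []
    counter = itertools.count()
    for amp in ref.amplicons:
        denom = (1 - truncated_fraction) * amp.length + truncated_fraction * mean_trunc
        n_total = depth * amp.length / denom if denom > 0 else 0
        n_full = int(round(n_total * (1 - truncated_fraction)))
        n_trunc = int(round(n_total * truncated_fraction))
        windows = [(amp.start, amp.end, None) for _ in range(n_full)]
        hi = min(4000, amp.length)
        for _ in range(n_trunc):
            span = int(rng.integers(500, hi + 1))
            windows.append((amp.start, amp.start + span, "+"))
        for ws, we, forced_strand in windows:
            seq, cigar, ref_start = _simulate_molecule(
                ref, arrays, ws, we, profile, rng
            )
            if not seq:
                continue
            strand = forced_strand or ("+" if rng.random() < 0.5 else "-")
            reads.append(
                AlignedRead(
                    read_id=f"{label}_L{next(counter):06d}",
                    platform="LONG",
                    ref_start=ref_start,
                    cigar=cigar,
                    seq=seq,
                    quals=np.full(len(seq), LONG_QUAL, dtype=np.uint8),
                    strand=strand,
                    contributor=hap.contributor_id,
                )
            )
    return reads


def simulate_mixture(
    ref: ReferenceGenome,
    hap_a: HaplotypeSpec,
    hap_b: HaplotypeSpec,
    ratio: tuple[float, float] = (0.5, 0.5),
    short_depth: float = 1000,
    long_depth: float = 300,
    short_profile: Optional[ErrorProfile] = None,
    long_profile: Optional[ErrorProfile] = None,
    seed: int = DEFAULT_SEED,
    sample: str = "mixture",
    **platform_kwargs,
) -> dict[str, list]:
    """Simulate a two-contributor mixture on both platforms.

    Molecules are drawn from the two haplotypes in the stated ratio (each
    contributor's expected molecule count is its ratio share of the total);
    per-read truth labels are retained.  Returns ``{"SHORT": [ReadPair...],
    "LONG": [AlignedRead...]}``.
    """
    if abs(sum(ratio) - 1.0) > 1e-9 or min(ratio) < 0:
        raise ConfigurationError(f"mixture ratio {ratio} must be non-negative and sum to 1")
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    short_kwargs = {
        k: platform_kwargs[k]
        for k in ("read_len", "frag_mean", "frag_sd")
        if k in platform_kwargs
    }
    long_kwargs = {
        k: platform_kwargs[k] for k in ("truncated_fraction",) if k in platform_kwargs
    }
    short_pairs: list[ReadPair] = []
    long_reads: list[AlignedRead] = []
    for hap, share, s_seed, l_seed in (
        (hap_a, ratio[0], seeds[0], seeds[1]),
        (hap_b, ratio[1], seeds[2], seeds[3]),
    ):
        if share == 0:
            continue
        short_pairs.extend(
            simulate_short_reads(
                ref, hap, short_depth * share, profile=short_profile,
                seed=int(s_seed), sample=sample, **short_kwargs,
            )
        )
        long_reads.extend(
            simulate_long_reads(
                ref, hap, long_depth * share, profile=long_profile,
                seed=int(l_seed), sample=sample, **long_kwargs,
            )
        )
    short_pairs.sort(key=lambda p: (min(p.r1.ref_start, p.r2.ref_start), p.pair_id))
    long_reads.sort(key=lambda r: (r.ref_start, r.read_id))
    return {"SHORT": short_pairs, "LONG": long_reads}
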