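"""Per-position allele counting, VAF computation and frequency-threshold SNP
calling, plus left-align/decompose variant normalization.

The caller is deliberately naive: a non-reference base is called a SNP wherever
its variant allele frequency (VAF) — the fraction of *all* reads covering the
position that carry the base, deletions and third alleles included in the
denominator — meets a global threshold.  No genotype likelihoods and no
base-quality weighting; the transparent analogue of a quality floor is a
minimum covering-read depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .reads import AlignedRead, MalformedAlignmentError, ReadPair
from .simdata import BASES, ReferenceGenome, Variant, encode


class UndefinedVAFError(ZeroDivisionError):
    """VAF requested at a position no read covers."""


@dataclass
class PileupColumn:
    """Allele counts at one reference position.

    ``depth`` counts every read whose alignment covers the position, whether
    it shows a base or a deletion; insertion events are anchored here (between
    this position and the next).
    """

    pos: int
    counts: dict[str, int]
    deletion_count: int
    insertion_events: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values()) + self.deletion_count


@dataclass(frozen=True)
class VariantCall:
    pos: int
    ref_allele: str
    alt_allele: str
    vaf: float
    depth: int
    vclass: str = "SNP"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt equals ref")


@dataclass
class CallSet:
    """SNP calls surviving a VAF threshold (one m_t / n_t subset)."""

    threshold: float
    calls: dict[tuple[int, str], VariantCall]
    platform: str = ""
    ploidy_mode: str = "single_source"

    @property
    def sites(self) -> set[tuple[int, str]]:
        return set(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self.calls


class Pileup:
    """Column store of allele counts over the whole reference.

    Acts as a sequence of :class:`PileupColumn`; internally numpy arrays of
    shape ``(L, 4)`` base counts, ``(L,)`` deletion counts, and a sparse map
    of insertion events keyed by anchor position.
    """

    def __init__(self, ref_length: int) -> None:
        self.base_counts = np.zeros((ref_length, 4), dtype=np.int32)
        self.deletion_counts = np.zeros(ref_length, dtype=np.int32)
        self.insertions: dict[int, dict[str, int]] = {}

    def __len__(self) -> int:
        return self.base_counts.shape[0]

    def __getitem__(self, pos: int) -> PileupColumn:
        counts = {BASES[i]: int(self.base_counts[pos, i]) for i in range(4)}
        return PileupColumn(
            pos=pos,
            counts=counts,
            deletion_count=int(self.deletion_counts[pos]),
            insertion_events=dict(self.insertions.get(pos, {})),
        )

    @property
    def depths(self) -> np.ndarray:
        return self.base_counts.sum(axis=1) + self.deletion_counts

    def add_read(self, read: AlignedRead) -> None:
        if not read.is_mapped or read.is_secondary:
            return
        if read.ref_end > len(self):
            raise MalformedAlignmentError(
                f"{read.read_id} extends past reference end"
            )
        codes = encode(read.seq)
        rpos, qpos = read.ref_start, 0
        for op, n in read.cigar:
            if op == "M":
                idx = np.arange(rpos, rpos + n)
                self.base_counts[idx, codes[qpos : qpos + n]] += 1
                rpos += n
                qpos += n
            elif op == "D":
                self.deletion_counts[rpos : rpos + n] += 1
                rpos += n
            elif op == "I":
                anchor = rpos - 1
                if anchor >= 0:
                    seq = read.seq[qpos : qpos + n]
                    bucket = self.insertions.setdefault(anchor, {})
                    bucket[seq] = bucket.get(seq, 0) + 1
                qpos += n
            elif op == "S":
                qpos += n


def _flatten(reads: Iterable) -> Iterable[AlignedRead]:
    for item in reads:
        if isinstance(item, ReadPair):
            yield item.r1
            yield item.r2
        else:
            yield item


def build_pileup(reads: Iterable, ref: ReferenceGenome) -> Pileup:
    """Accumulate allele counts from reads (``AlignedRead`` or ``ReadPair``).

    Secondary and unmapped records contribute nothing; a read extending past
    the reference end raises :class:`MalformedAlignmentError`.
    """
    pile = Pileup(len(ref))
    for read in _flatten(reads):
        pile.add_read(read)
    return pile


def vaf(column: PileupColumn, allele: str) -> float:
    """Fraction of covering reads showing ``allele`` at this column.

    The denominator is total covering depth: matching reads, other bases and
    deletion-spanning reads all count.
    """
    depth = column.depth
    if depth == 0:
        raise UndefinedVAFError(f"no coverage at position {column.pos}")
    return column.counts.get(allele, 0) / depth


def call_snps(
    pileup: Pileup,
    ref: ReferenceGenome,
    threshold: float,
    min_depth: int = 20,
    ploidy_mode: str = "single_source",
    platform: str = "",
) -> CallSet:
    """Threshold the pileup into a SNP call set.

    Insertion and deletion signals never yield calls (SNP-only filter).  In
    ``single_source`` mode at most the single highest-VAF alternate base is
    kept per position; in ``mixture`` mode up to two alternates may be kept
    (the observable effect of calling at ploidy 2).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    if ploidy_mode not in ("single_source", "mixture"):
        raise ValueError(f"unknown ploidy mode {ploidy_mode!r}")
    depths = pileup.depths
    with np.errstate(invalid="ignore", divide="ignore"):
        vafs = pileup.base_counts / np.maximum(depths, 1)[:, None]
    ref_codes = ref.codes
    eligible = (depths >= min_depth)[:, None] & (vafs >= threshold)
    eligible[np.arange(len(ref)), ref_codes] = False  # never call the ref base
    max_alts = 1 if ploidy_mode == "single_source" else 2
    calls: dict[tuple[int, str], VariantCall] = {}
    for pos in np.flatnonzero(eligible.any(axis=1)):
        pos = int(pos)
        alt_codes = np.flatnonzero(eligible[pos])
        order = alt_codes[np.argsort(-vafs[pos, alt_codes], kind="stable")]
        for code in order[:max_alts]:
            alt = BASES[int(code)]
            calls[(pos, alt)] = VariantCall(
                pos=pos,
                ref_allele=ref.sequence[pos],
                alt_allele=alt,
                vaf=float(vafs[pos, code]),
                depth=int(depths[pos]),
            )
    return CallSet(
        threshold=threshold, calls=calls, platform=platform, ploidy_mode=ploidy_mode
    )


# ---------------------------------------------------------------------------
# variant normalization (left-align + decompose)


class ReferenceMismatchError(ValueError):
    """A variant's stated reference allele disagrees with the reference."""


def _check_ref(v: Variant, ref: ReferenceGenome) -> None:
    window = ref.sequence[v.pos : v.pos + len(v.ref_allele)]
    if window != v.ref_allele:
        raise ReferenceMismatchError(
            f"variant at {v.pos}: ref allele {v.ref_allele!r} but reference "
            f"has {window!r}"
        )


def left_align_and_decompose(
    variants: Sequence[Variant], ref: ReferenceGenome
) -> list[Variant]:
    """Normalize a variant list: split multi-allelic records and block
    substitutions into primitive biallelic calls, and shift indels left
    through repeated sequence.  Idempotent; output sorted by position.
    """
    out: list[Variant] = []
    queue: list[Variant] = []
    for v in variants:
        if "," in v.alt_allele:  # multi-allelic record → biallelic records
            queue.extend(
                Variant(v.pos, v.ref_allele, alt) for alt in v.alt_allele.split(",")
            )
        else:
            queue.append(v)
    for v in queue:
        _check_ref(v, ref)
        ra, aa = v.ref_allele, v.alt_allele
        if len(ra) == len(aa):
            # block substitution → per-position SNPs at differing offsets
            out.extend(
                Variant(v.pos + i, ra[i], aa[i])
                for i in range(len(ra))
                if ra[i] != aa[i]
            )
            continue
        out.append(_left_align_indel(v, ref))
    return sorted(set(out))


def _left_align_indel(v: Variant, ref: ReferenceGenome) -> Variant:
    pos, ra, aa = v.pos, v.ref_allele, v.alt_allele
    while True:
        # trim identical trailing base, pulling in the preceding reference base
        if len(ra) > 1 and len(aa) > 1 and ra[-1] == aa[-1]:
            ra, aa = ra[:-1], aa[:-1]
            continue
        if len(ra) > 1 and len(aa) > 1 and ra[0] == aa[0]:
            pos += 1
            ra, aa = ra[1:], aa[1:]
            continue
        if ra[-1] == aa[-1] and pos > 0:
            prev = ref.sequence[pos - 1]
            ra, aa = prev + ra[:-1], prev + aa[:-1]
            pos -= 1
            continue
        break
    return Variant(pos, ra, aa)
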