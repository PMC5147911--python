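"""Per-contributor consensus reconstruction and assembly statistics.

Reference-guided consensus: phased long reads and deconvolved short reads are
pooled into one pileup, and every alternate signal (SNP, insertion or
deletion) reaching the reconstruction VAF — 0.75 by default — is applied to
the reference.  The supporting call set is classified against the
contributor's truth variants.  Nx and NGAx curves are computed from contig
lengths (and alignment-block lengths plus a genome size for NGAx) exactly as
assembly evaluators define them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pileup import Pileup, build_pileup
from .reads import AlignedRead, ReadPair
from .simdata import BASES, HaplotypeSpec, ReferenceGenome, Variant


@dataclass
class ConsensusResult:
    contributor_id: str
    sequence: str
    supporting_calls: list[Variant]
    gaps: list[tuple[int, int]]  # uncovered reference intervals (N-filled)
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def concordant(self) -> bool:
        return self.fp == 0 and self.fn == 0


def reconstruct_contributor(
    phased_long: Sequence[AlignedRead],
    deconvolved_short: Sequence[ReadPair],
    ref: ReferenceGenome,
    vaf: float = 0.75,
    min_depth: int = 1,
    contributor_id: str = "",
    truth: Optional[HaplotypeSpec] = None,
) -> ConsensusResult:
    """Rebuild one contributor's genome from its merged read pools.

    At each position the dominant signal wins when it reaches ``vaf``:
    a non-reference base substitutes, a deletion excises, and an insertion
    (majority inserted sequence at the anchor) is spliced in after the
    anchor base.  Uncovered positions are N-filled and reported as gaps.
    """
    merged: list = list(phased_long) + list(deconvolved_short)
    if not merged:
        raise ValueError("cannot reconstruct from an empty read pool")
    pile = build_pileup(merged, ref)
    depths = pile.depths
    calls: list[Variant] = []

    consensus: list[str] = []
    gaps: list[tuple[int, int]] = []
    gap_start: Optional[int] = None
    length = len(ref)
    base_counts = pile.base_counts
    del_counts = pile.deletion_counts

    # positions worth a python-level look: any alt/del/ins signal at >= vaf
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = base_counts / np.maximum(depths, 1)[:, None]
    alt_mask = frac >= vaf
    alt_mask[np.arange(length), ref.codes] = False
    del_mask = (del_counts / np.maximum(depths, 1)) >= vaf
    hot = set(np.flatnonzero(alt_mask.any(axis=1)).tolist())
    hot |= set(np.flatnonzero(del_mask).tolist())
    hot |= set(pile.insertions)

    for pos in range(length):
        depth = int(depths[pos])
        if depth < min_depth:
            consensus.append("N")
            if gap_start is None:
                gap_start = pos
            continue
        if gap_start is not None:
            gaps.append((gap_start, pos))
            gap_start = None
        ref_base = ref.sequence[pos]
        emitted = ref_base
        if pos in hot:
            if del_mask[pos]:
                calls.append(_del_variant(ref, pos))
                emitted = ""
            else:
                alt_codes = np.flatnonzero(alt_mask[pos])
                if alt_codes.size:
                    code = alt_codes[int(np.argmax(frac[pos, alt_codes]))]
                    emitted = BASES[int(code)]
                    calls.append(Variant(pos, ref_base, emitted))
            ins_bucket = pile.insertions.get(pos, {})
            if ins_bucket:
                total_ins = sum(ins_bucket.values())
                if total_ins / depth >= vaf:
                    seq = max(sorted(ins_bucket), key=lambda s: ins_bucket[s])
                    emitted += seq
                    calls.append(Variant(pos, ref_base, ref_base + seq))
        consensus.append(emitted)
    if gap_start is not None:
        gaps.append((gap_start, length))

    result = ConsensusResult(
        contributor_id=contributor_id,
        sequence="".join(consensus),
        supporting_calls=sorted(calls),
        gaps=gaps,
    )
    if truth is not None:
        truth_keys = {(v.pos, v.alt_allele) for v in truth.all_variants}
        call_keys = {(v.pos, v.alt_allele) for v in calls}
        result.tp = len(truth_keys & call_keys)
        result.fp = len(call_keys - truth_keys)
        result.fn = len(truth_keys - call_keys)
    return result


def _del_variant(ref: ReferenceGenome, pos: int) -> Variant:
    # single-base deletion anchored at the preceding base
    anchor = max(pos - 1, 0)
    return Variant(anchor, ref.sequence[anchor : pos + 1], ref.sequence[anchor])


# ---------------------------------------------------------------------------
# assembly statistics


@dataclass
class AssemblyStats:
    """Contig-length statistics: the Nx curve and, when alignment-block
    lengths and a genome size are supplied, the NGAx curve."""

    contig_lengths: list[int]
    total_length: int
    nx: dict[int, int]  # x (1..100) -> Nx
    n50: int
    genome_size: Optional[int] = None
    aligned_blocks: Optional[list[int]] = None
    ngax: Optional[dict[int, Optional[int]]] = None
    nga50: Optional[int] = None


def nx_curve(contig_lengths: Sequence[int]) -> AssemblyStats:
    """Nx for integer x in 1..100.

    Nx is the length of the smallest contig in the minimal set of largest
    contigs whose summed length reaches x% of the total assembly length.
    """
    lengths = sorted((int(c) for c in contig_lengths), reverse=True)
    if not lengths or lengths[-1] <= 0:
        raise ValueError("contig lengths must be a non-empty list of positive ints")
    total = sum(lengths)
    cumulative = np.cumsum(lengths)
    nx: dict[int, int] = {}
    for x in range(1, 101):
        target = total * x / 100
        idx = int(np.searchsorted(cumulative, target, side="left"))
        nx[x] = lengths[min(idx, len(lengths) - 1)]
    return AssemblyStats(
        contig_lengths=lengths, total_length=total, nx=nx, n50=nx[50]
    )


def ngax_curve(
    aligned_blocks: Sequence[int], genome_size: int
) -> AssemblyStats:
    """NGAx: like Nx but thresholds are x% of the *genome* size and the
    inputs are alignment-broken block lengths.  Undefined (None) for x
    beyond the fraction of the genome the blocks cover."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    blocks = sorted((int(b) for b in aligned_blocks), reverse=True)
    if not blocks or blocks[-1] <= 0:
        raise ValueError("aligned blocks must be a non-empty list of positive ints")
    total = sum(blocks)
    cumulative = np.cumsum(blocks)
    ngax: dict[int, Optional[int]] = {}
    for x in range(1, 101):
        target = genome_size * x / 100
        if total < target:
            ngax[x] = None
            continue
        idx = int(np.searchsorted(cumulative, target, side="left"))
        ngax[x] = blocks[min(idx, len(blocks) - 1)]
    stats = nx_curve(blocks)
    stats.genome_size = genome_size
    stats.aligned_blocks = blocks
    stats.ngax = ngax
    stats.nga50 = ngax[50]
    return stats


def consensus_contigs(result: ConsensusResult) -> list[int]:
    """Contig lengths of a consensus: runs of called sequence between gaps."""
    contigs = []
    run = 0
    for ch in result.sequence:
        if ch == "N":
            if run:
                contigs.append(run)
            run = 0
        else:
            run += 1
    if run:
        contigs.append(run)
    return contigs


# ---------------------------------------------------------------------------
# coverage


def coverage_track(reads: Iterable, ref: ReferenceGenome) -> np.ndarray:
    """Per-base depth over the reference (M and D spans both cover)."""
    depth = np.zeros(len(ref), dtype=np.int64)
    from .pileup import _flatten  # local import to avoid a cycle at import time

    for read in _flatten(reads):
        if read.is_mapped and not read.is_secondary:
            depth[read.ref_start : read.ref_end] += 1
    return depth


def coverage_summary(depth: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(depth, [25, 50, 75])
    return dict(
        mean=float(depth.mean()), median=float(med),
        q1=float(q1), q3=float(q3),
        min=int(depth.min()), max=int(depth.max()),
    )
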