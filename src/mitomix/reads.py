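"""SAM-level read records and CIGAR arithmetic.

Every stage of the pipeline exchanges :class:`AlignedRead` objects: simulator
output, pileup input, phasing/deconvolution units.  Reads are stored in
reference orientation (as in a SAM file); ``strand`` records the orientation
of the original molecule and only matters when exporting FASTQ.

CIGAR operations are restricted to M (alignment match/mismatch), I (insertion
to the reference), D (deletion from the reference) and S (soft clip).  An
insertion is anchored at the *preceding* consumed reference position: an I op
that falls between reference positions p and p+1 has anchor p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

Cigar = list[tuple[str, int]]

QUERY_OPS = frozenset("MIS")
REF_OPS = frozenset("MD")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MalformedAlignmentError(ValueError):
    """A read's CIGAR, sequence and placement are mutually inconsistent."""


def cigar_query_length(cigar: Cigar) -> int:
    """Number of query bases consumed (M + I + S)."""
    return sum(n for op, n in cigar if op in QUERY_OPS)


def cigar_reference_span(cigar: Cigar) -> int:
    """Number of reference bases consumed (M + D)."""
    return sum(n for op, n in cigar if op in REF_OPS)


def cigar_to_string(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def parse_cigar(text: str) -> Cigar:
    out: Cigar = []
    n = ""
    for ch in text:
        if ch.isdigit():
            n += ch
        else:
            if not n or ch not in "MIDS":
                raise MalformedAlignmentError(f"unsupported CIGAR: {text!r}")
            out.append((ch, int(n)))
            n = ""
    if n:
        raise MalformedAlignmentError(f"truncated CIGAR: {text!r}")
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignedRead:
    """One aligned sequencing read with its simulation truth label.

    ``ref_start`` is 0-based; the reference span is ``[ref_start, ref_end)``.
    ``contributor`` is the truth label of the molecule of origin (``None`` for
    reads loaded from a SAM that carries no ``XC`` tag).
    """

    read_id: str
    platform: str  # "SHORT" | "LONG"
    ref_start: int
    cigar: Cigar
    seq: str
    quals: np.ndarray
    strand: str = "+"
    contributor: Optional[str] = None
    pair_id: Optional[str] = None
    mate: Optional[int] = None  # 1 or 2 for paired short reads
    is_mapped: bool = True
    is_secondary: bool = False

    @property
    def query_length(self) -> int:
        return cigar_query_length(self.cigar)

    @property
    def reference_span(self) -> int:
        return cigar_reference_span(self.cigar)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.reference_span

    def covers(self, pos: int) -> bool:
        return self.ref_start <= pos < self.ref_end

    def validate(self, ref_length: Optional[int] = None) -> None:
        """Check CIGAR/sequence consistency and reference bounds."""
        if cigar_query_length(self.cigar) != len(self.seq):
            raise MalformedAlignmentError(
                f"{self.read_id}: CIGAR consumes {cigar_query_length(self.cigar)} "
                f"query bases but sequence has {len(self.seq)}"
            )
        if len(self.quals) != len(self.seq):
            raise MalformedAlignmentError(f"{self.read_id}: qual/seq length mismatch")
        if self.ref_start < 0:
            raise MalformedAlignmentError(f"{self.read_id}: negative reference start")
        if ref_length is not None and self.ref_end > ref_length:
            raise MalformedAlignmentError(
                f"{self.read_id}: alignment ends at {self.ref_end} past reference "
                f"end {ref_length}"
            )

    def base_at(self, pos: int) -> tuple[Optional[str], str]:
        """Observed base and covering CIGAR op at reference position ``pos``.

        Returns ``(base, 'M')`` when the position is aligned, ``(None, 'D')``
        under a deletion, and ``(None, '.')`` when the read does not cover the
        position at all.
        """
        if not self.covers(pos):
            return None, "."
        rpos = self.ref_start
        qpos = 0
        for op, n in self.cigar:
            if op == "M":
                if rpos <= pos < rpos + n:
                    return self.seq[qpos + (pos - rpos)], "M"
                rpos += n
                qpos += n
            elif op == "D":
                if rpos <= pos < rpos + n:
                    return None, "D"
                rpos += n
            elif op in "IS":
                qpos += n
        return None, "."

    def insertion_at(self, anchor: int) -> Optional[str]:
        """Inserted sequence anchored at reference position ``anchor``, if any."""
        rpos = self.ref_start
        qpos = 0
        for op, n in self.cigar:
            if op == "M":
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            elif op == "I":
                if rpos - 1 == anchor:
                    return self.seq[qpos : qpos + n]
                qpos += n
            elif op == "S":
                qpos += n
        return None

    def oriented_seq_quals(self) -> tuple[str, np.ndarray]:
        """Sequence and qualities in original-molecule orientation (for FASTQ)."""
        if self.strand == "-":
            return reverse_complement(self.seq), self.quals[::-1]
        return self.seq, self.quals


@dataclass
class ReadPair:
    """A proper short-read pair; mates always travel together."""

    r1: AlignedRead
    r2: AlignedRead

    @property
    def pair_id(self) -> str:
        return self.r1.pair_id or self.r1.read_id

    @property
    def contributor(self) -> Optional[str]:
        return self.r1.contributor

    @property
    def mates(self) -> tuple[AlignedRead, AlignedRead]:
        return (self.r1, self.r2)

    def covers(self, pos: int) -> bool:
        return self.r1.covers(pos) or self.r2.covers(pos)


def slice_alignment(read_seq: str, cigar: Cigar, ref_start: int, q0: int, q1: int
                    ) -> tuple[str, Cigar, int]:
    """Extract the sub-alignment covering query interval ``[q0, q1)``.

    Returns the sub-sequence, its CIGAR and its reference start.  Deletions at
    the boundary of the slice are dropped (a SAM record may not begin or end
    with D).  Used to cut mate reads out of a simulated fragment alignment.
    """
    if not 0 <= q0 < q1 <= cigar_query_length(cigar):
        raise ValueError(f"bad query slice [{q0}, {q1})")
    out: Cigar = []
    rpos = ref_start
    qpos = 0
    slice_ref_start = None
    for op, n in cigar:
        if op in QUERY_OPS:
            lo, hi = max(qpos, q0), min(qpos + n, q1)
            if lo < hi:
                if op == "M" and slice_ref_start is None:
                    slice_ref_start = rpos + (lo - qpos)
                out.append((op, hi - lo))
            qpos += n
            if op == "M":
                rpos += n
        else:  # D
            if q0 < qpos < q1 and out:
                out.append((op, n))
            rpos += n
    # a SAM record may not begin or end with D or I: trim, keeping seq in step
    trim_front = trim_back = 0
    while out and out[0][0] in "DI":
        op, n = out.pop(0)
        if op == "I":
            trim_front += n
    while out and out[-1][0] in "DI":
        op, n = out.pop()
        if op == "I":
            trim_back += n
    merged: Cigar = []
    for op, n in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    if slice_ref_start is None or not merged:
        raise ValueError("slice contains no aligned bases")
    return read_seq[q0 + trim_front : q1 - trim_back], merged, slice_ref_start


def validate_reads(reads: Iterable[AlignedRead], ref_length: int) -> None:
    for r in reads:
        r.validate(ref_length)
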