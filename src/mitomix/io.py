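"""File formats: SAM (pysam), FASTA (Biopython), and the pipeline's
tab-separated side formats (truth variant tables, private-variant panels,
heterozygous-site lists, BED-graph depth tracks).

Truth tables are VCF-like TSVs with columns CHROM, POS (1-based), REF, ALT,
CLASS (SNP/INS/DEL) and SHARING (``shared`` or ``private:<contributor>``).
All positions in files are 1-based; everything in memory is 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .deconvolution import PanelInsertion, PanelSNP, PrivateVariantPanel
from .phasing import HetSite
from .reads import AlignedRead, Cigar, ReadPair, cigar_to_string, parse_cigar
from .simdata import AmpliconDef, HaplotypeSpec, ReferenceGenome, Variant

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(ref: ReferenceGenome, path: PathLike) -> None:
    record = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: PathLike, name: Optional[str] = None) -> ReferenceGenome:
    """Load a reference; homopolymer runs of >= 5 are re-annotated by scan and
    amplicons are left empty (they live in the run manifest)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    return ReferenceGenome(
        name=name or record.id,
        sequence=seq,
        homopolymers=scan_homopolymers(seq, min_run=5),
    )


def scan_homopolymers(seq: str, min_run: int = 5) -> list[tuple[int, int, str]]:
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


# ---------------------------------------------------------------------------
# SAM

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_MREVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80
_FLAG_SECONDARY = 0x100


def _header(ref: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref.name, "LN": len(ref)}],
        }
    )


def _to_segment(
    read: AlignedRead,
    header: pysam.AlignmentHeader,
    mate: Optional[AlignedRead] = None,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.read_id.rsplit("/", 1)[0] if read.pair_id else read.read_id
    seg.reference_id = 0
    seg.reference_start = read.ref_start
    seg.mapping_quality = 60
    seg.cigarstring = cigar_to_string(read.cigar)
    seg.query_sequence = read.seq
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(int(q) + 33) for q in read.quals)
    )
    flag = 0
    if read.strand == "-":
        flag |= _FLAG_REVERSE
    if not read.is_mapped:
        flag |= _FLAG_UNMAPPED
    if read.is_secondary:
        flag |= _FLAG_SECONDARY
    if mate is not None:
        flag |= _FLAG_PAIRED | _FLAG_PROPER
        flag |= _FLAG_READ1 if read.mate == 1 else _FLAG_READ2
        if mate.strand == "-":
            flag |= _FLAG_MREVERSE
        seg.next_reference_id = 0
        seg.next_reference_start = mate.ref_start
        lo = min(read.ref_start, mate.ref_start)
        hi = max(read.ref_end, mate.ref_end)
        seg.template_length = (hi - lo) if read.ref_start <= mate.ref_start else -(hi - lo)
    else:
        seg.next_reference_id = -1
        seg.next_reference_start = -1
    seg.flag = flag
    tags = [("XP", read.platform)]
    if read.contributor:
        tags.append(("XC", read.contributor))
    seg.set_tags(tags)
    return seg


def write_sam(
    reads: Iterable[Union[AlignedRead, ReadPair]],
    ref: ReferenceGenome,
    path: PathLike,
) -> int:
    """Write reads/pairs as a coordinate-sorted SAM; returns records written."""
    header = _header(ref)
    segments = []
    for item in reads:
        if isinstance(item, ReadPair):
            segments.append(_to_segment(item.r1, header, mate=item.r2))
            segments.append(_to_segment(item.r2, header, mate=item.r1))
        else:
            segments.append(_to_segment(item, header))
    segments.sort(key=lambda s: (s.reference_start, s.query_name, s.flag))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            out.write(seg)
    return len(segments)


def _from_segment(seg: pysam.AlignedSegment) -> AlignedRead:
    cigar: Cigar = parse_cigar(seg.cigarstring) if seg.cigarstring else []
    quals = (
        np.array(seg.query_qualities, dtype=np.uint8)
        if seg.query_qualities is not None
        else np.zeros(len(seg.query_sequence or ""), dtype=np.uint8)
    )
    paired = bool(seg.flag & _FLAG_PAIRED)
    mate = None
    if paired:
        mate = 1 if seg.flag & _FLAG_READ1 else 2
    return AlignedRead(
        read_id=f"{seg.query_name}/{mate}" if paired else seg.query_name,
        platform=seg.get_tag("XP") if seg.has_tag("XP") else "UNKNOWN",
        ref_start=seg.reference_start,
        cigar=cigar,
        seq=seg.query_sequence or "",
        quals=quals,
        strand="-" if seg.flag & _FLAG_REVERSE else "+",
        contributor=seg.get_tag("XC") if seg.has_tag("XC") else None,
        pair_id=seg.query_name if paired else None,
        mate=mate,
        is_mapped=not bool(seg.flag & _FLAG_UNMAPPED),
        is_secondary=bool(seg.flag & _FLAG_SECONDARY),
    )


def read_sam(path: PathLike) -> list[AlignedRead]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as f:
        return [_from_segment(seg) for seg in f]


def group_pairs(reads: Sequence[AlignedRead]) -> list[ReadPair]:
    """Group paired reads by pair id (mate 1 first); orphans are dropped."""
    by_pair: dict[str, dict[int, AlignedRead]] = {}
    order: list[str] = []
    for r in reads:
        if r.pair_id is None or r.mate is None:
            continue
        if r.pair_id not in by_pair:
            order.append(r.pair_id)
        by_pair.setdefault(r.pair_id, {})[r.mate] = r
    pairs = []
    for pid in order:
        mates = by_pair[pid]
        if 1 in mates and 2 in mates:
            pairs.append(ReadPair(mates[1], mates[2]))
    return pairs


# ---------------------------------------------------------------------------
# tab-separated side formats


def write_truth_table(
    haps: Sequence[HaplotypeSpec], ref: ReferenceGenome, path: PathLike
) -> pd.DataFrame:
    """Union of contributors' variants with sharing labels, 1-based POS."""
    rows = {}
    for hap in haps:
        for v in hap.shared_variants:
            rows[(v.pos, v.alt_allele)] = dict(
                CHROM=ref.name, POS=v.pos + 1, REF=v.ref_allele, ALT=v.alt_allele,
                CLASS=v.vclass, SHARING="shared",
            )
        for v in hap.private_variants:
            rows[(v.pos, v.alt_allele)] = dict(
                CHROM=ref.name, POS=v.pos + 1, REF=v.ref_allele, ALT=v.alt_allele,
                CLASS=v.vclass, SHARING=f"private:{hap.contributor_id}",
            )
    df = pd.DataFrame([rows[k] for k in sorted(rows)])
    df.to_csv(path, sep="\t", index=False)
    return df


def read_truth_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def truth_variants(df: pd.DataFrame, sharing_prefix: str = "") -> list[Variant]:
    sub = df[df["SHARING"].str.startswith(sharing_prefix)] if sharing_prefix else df
    return [
        Variant(int(r.POS) - 1, r.REF, r.ALT) for r in sub.itertuples(index=False)
    ]


def write_panel(panel: PrivateVariantPanel, path: PathLike) -> None:
    rows = [
        dict(POS=s.pos + 1, TYPE="SNP", ALLELE_A=s.allele_a, ALLELE_B=s.allele_b,
             INS_SEQ="", CARRIER="")
        for s in panel.snps
    ] + [
        dict(POS=i.pos + 1, TYPE="INS", ALLELE_A="", ALLELE_B="",
             INS_SEQ=i.inserted_seq, CARRIER=i.carrier)
        for i in panel.insertions
    ]
    pd.DataFrame(rows).sort_values("POS").to_csv(path, sep="\t", index=False)


def read_panel(path: PathLike) -> PrivateVariantPanel:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    snps = [
        PanelSNP(int(r.POS) - 1, r.ALLELE_A, r.ALLELE_B)
        for r in df[df.TYPE == "SNP"].itertuples(index=False)
    ]
    ins = [
        PanelInsertion(int(r.POS) - 1, r.INS_SEQ, r.CARRIER)
        for r in df[df.TYPE == "INS"].itertuples(index=False)
    ]
    return PrivateVariantPanel(snps, ins)


def write_het_sites(sites: Sequence[HetSite], path: PathLike) -> None:
    pd.DataFrame(
        [dict(POS=p + 1, ALLELE_A=a, ALLELE_B=b) for p, a, b in sites]
    ).to_csv(path, sep="\t", index=False)


def read_het_sites(path: PathLike) -> list[HetSite]:
    df = pd.read_csv(path, sep="\t")
    return [(int(r.POS) - 1, r.ALLELE_A, r.ALLELE_B) for r in df.itertuples(index=False)]


def write_bedgraph(depth: np.ndarray, ref: ReferenceGenome, path: PathLike) -> None:
    """Run-length encoded per-base depth (chrom, start, end, depth)."""
    with open(path, "w") as out:
        start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[start]:
                out.write(f"{ref.name}\t{start}\t{i}\t{int(depth[start])}\n")
                start = i


def write_concordance_bed(result, ref: ReferenceGenome, path: PathLike) -> None:
    """Per-site concordance track: one BED line (0-based half-open) per
    classified site, named ``<alt>:<TP|FP|FN>``."""
    rows = []
    for category, sites in (("TP", result.tp_sites), ("FP", result.fp_sites),
                            ("FN", result.fn_sites)):
        rows.extend((pos, alt, category) for pos, alt in sites)
    with open(path, "w") as out:
        for pos, alt, category in sorted(rows):
            out.write(f"{ref.name}\t{pos}\t{pos + 1}\t{alt}:{category}\n")


def write_call_set(calls, path: PathLike, ref_name: str = "") -> None:
    rows = [
        dict(CHROM=ref_name, POS=c.pos + 1, REF=c.ref_allele, ALT=c.alt_allele,
             VAF=round(c.vaf, 6), DEPTH=c.depth, CLASS=c.vclass)
        for c in sorted(calls.calls.values(), key=lambda c: (c.pos, c.alt_allele))
    ]
    pd.DataFrame(
        rows, columns=["CHROM", "POS", "REF", "ALT", "VAF", "DEPTH", "CLASS"]
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True)
        f.write("\n")
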