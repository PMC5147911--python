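"""Short-read mixture deconvolution by private variants.

Every read pair from the mixture alignment is queried at the panel of private
SNPs and private insertions.  At a SNP the base under the alignment is
informative only when the covering CIGAR op is a match (M) and the base equals
one contributor's allele.  At an insertion the pair must align within 10 bp on
both sides of the insertion site; an insert (I) op at the site attributes the
pair to the carrier, otherwise to the other contributor.  Verdicts across all
covered panel sites are aggregated by majority; ties and uninformative pairs
fall into the shared pool.  Each contributor's deconvolved set is its private
pool plus the shared pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .reads import AlignedRead, ReadPair
from .simdata import HaplotypeSpec, ReferenceGenome, Variant

INSERTION_WINDOW = 10  # bp of required anchoring on each side of an insertion


@dataclass(frozen=True)
class PanelSNP:
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"panel SNP at {self.pos} has identical alleles")


@dataclass(frozen=True)
class PanelInsertion:
    pos: int  # anchor: insertion sits between pos and pos + 1
    inserted_seq: str
    carrier: str  # "A" | "B"


@dataclass
class PrivateVariantPanel:
    """Private SNPs and insertions distinguishing the two contributors."""

    snps: list[PanelSNP]
    insertions: list[PanelInsertion]

    def __post_init__(self) -> None:
        positions = [s.pos for s in self.snps] + [i.pos for i in self.insertions]
        if len(positions) != len(set(positions)):
            raise ValueError("panel positions must be unique")

    def swapped(self) -> "PrivateVariantPanel":
        """The same panel with contributor labels exchanged."""
        return PrivateVariantPanel(
            snps=[PanelSNP(s.pos, s.allele_b, s.allele_a) for s in self.snps],
            insertions=[
                PanelInsertion(i.pos, i.inserted_seq, "B" if i.carrier == "A" else "A")
                for i in self.insertions
            ],
        )


def panel_from_haplotypes(
    ref: ReferenceGenome, hap_a: HaplotypeSpec, hap_b: HaplotypeSpec
) -> PrivateVariantPanel:
    """Build the private-variant panel from two truth haplotypes.

    At a private SNP of one contributor, the other contributor carries the
    reference base.
    """
    snps, insertions = [], []
    for hap, own, other in ((hap_a, "A", "B"), (hap_b, "B", "A")):
        for v in hap.private_variants:
            if v.vclass == "SNP":
                alleles = (
                    (v.alt_allele, v.ref_allele)
                    if own == "A"
                    else (v.ref_allele, v.alt_allele)
                )
                snps.append(PanelSNP(v.pos, *alleles))
            elif v.vclass == "INS":
                insertions.append(PanelInsertion(v.pos, v.alt_allele[1:], own))
    return PrivateVariantPanel(sorted(snps, key=lambda s: s.pos),
                               sorted(insertions, key=lambda i: i.pos))


@dataclass
class Evidence:
    pair_id: str
    site: int
    kind: str  # "SNP" | "INS"
    observed: str
    cigar_op: str
    verdict: str


@dataclass
class ReadPoolAssignment:
    pool_a: list[ReadPair]
    pool_b: list[ReadPair]
    shared: list[ReadPair]
    evidence: list[Evidence] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pool_a) + len(self.pool_b) + len(self.shared)


def assign_pair_by_snp(pair: ReadPair, site: PanelSNP) -> str:
    """Verdict ("A", "B" or "no_evidence") for one pair at one private SNP.

    Each mate covering the site contributes: a base under an M op equal to a
    contributor's allele votes for that contributor; a deletion, clip, or a
    third allele is no evidence.  Mates that disagree cancel out.
    """
    if not pair.covers(site.pos):
        raise ValueError(f"pair {pair.pair_id} does not cover position {site.pos}")
    verdicts = set()
    for mate in pair.mates:
        base, op = mate.base_at(site.pos)
        if op != "M":
            continue
        if base == site.allele_a:
            verdicts.add("A")
        elif base == site.allele_b:
            verdicts.add("B")
    if len(verdicts) == 1:
        return verdicts.pop()
    return "no_evidence"


def _pair_covers(pair: ReadPair, pos: int) -> bool:
    return any(m.covers(pos) for m in pair.mates)


def assign_pair_by_insertion(pair: ReadPair, ins: PanelInsertion) -> str:
    """Verdict ("A", "B" or "no_evidence") for one pair at a private insertion.

    Eligibility requires the pair's alignments to cover both flanking
    positions ``pos - 10`` and ``pos + 10``.  An eligible pair with an I op
    anchored at the site goes to the carrier; an eligible pair without one
    goes to the other contributor.
    """
    if not (
        _pair_covers(pair, ins.pos - INSERTION_WINDOW)
        and _pair_covers(pair, ins.pos + INSERTION_WINDOW)
    ):
        return "no_evidence"
    has_insert = any(m.insertion_at(ins.pos) is not None for m in pair.mates)
    if has_insert:
        return ins.carrier
    return "B" if ins.carrier == "A" else "A"


def deconvolve(
    pairs: Iterable[ReadPair], panel: PrivateVariantPanel
) -> ReadPoolAssignment:
    """Route every mixture read pair to pool A, pool B or the shared pool.

    A pair is evaluated at every panel site it covers; verdicts are
    aggregated by majority, with ties and zero evidence conservatively kept
    shared.  Secondary alignments are excluded from routing.
    """
    assignment = ReadPoolAssignment([], [], [])
    for pair in pairs:
        if any(m.is_secondary or not m.is_mapped for m in pair.mates):
            assignment.shared.append(pair)
            continue
        votes = {"A": 0, "B": 0}
        for snp in panel.snps:
            if not _pair_covers(pair, snp.pos):
                continue
            verdict = assign_pair_by_snp(pair, snp)
            base, op = next(
                (m.base_at(snp.pos) for m in pair.mates if m.covers(snp.pos)),
                (None, "."),
            )
            assignment.evidence.append(
                Evidence(pair.pair_id, snp.pos, "SNP", base or "-", op, verdict)
            )
            if verdict in votes:
                votes[verdict] += 1
        for ins in panel.insertions:
            if not (_pair_covers(pair, ins.pos - INSERTION_WINDOW)
                    or _pair_covers(pair, ins.pos + INSERTION_WINDOW)):
                continue
            verdict = assign_pair_by_insertion(pair, ins)
            has_i = any(m.insertion_at(ins.pos) is not None for m in pair.mates)
            assignment.evidence.append(
                Evidence(pair.pair_id, ins.pos, "INS",
                         ins.inserted_seq if has_i else "-",
                         "I" if has_i else "M", verdict)
            )
            if verdict in votes:
                votes[verdict] += 1
        if votes["A"] > votes["B"]:
            assignment.pool_a.append(pair)
        elif votes["B"] > votes["A"]:
            assignment.pool_b.append(pair)
        else:
            assignment.shared.append(pair)
    return assignment


def build_deconvolved_sets(
    assignment: ReadPoolAssignment,
) -> tuple[list[ReadPair], list[ReadPair]]:
    """Each contributor's read set: its private pool plus all shared pairs."""
    set_a = assignment.pool_a + assignment.shared
    set_b = assignment.pool_b + assignment.shared
    return set_a, set_b


def export_fastq(
    pairs: Sequence[ReadPair], r1_path, r2_path
) -> tuple[int, list[str]]:
    """Write proper pairs to an R1/R2 FASTQ file pair.

    Only pairs with both mates mapped and neither secondary are emitted, in
    input order; reverse-strand mates are written in original-molecule
    orientation.  Returns (records written, excluded pair ids).
    """
    written = 0
    excluded: list[str] = []
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for pair in pairs:
            ok = all(m.is_mapped and not m.is_secondary for m in pair.mates)
            if not ok:
                excluded.append(pair.pair_id)
                continue
            for mate, handle in ((pair.r1, f1), (pair.r2, f2)):
                seq, quals = mate.oriented_seq_quals()
                qual_str = "".join(chr(q + 33) for q in quals)
                handle.write(f"@{pair.pair_id}/{mate.mate}\n{seq}\n+\n{qual_str}\n")
            written += 2
    return written, excluded
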