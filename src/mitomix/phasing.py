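"""Long-read phasing: extract amplicon-spanning molecules and partition them
into two contributor pools by their alleles at known heterozygous sites.

Only reads long enough to be fully extended amplicon products are phased:
membership in a spanning set requires the read's reference span to intersect
the extraction interval *and* its query length to exceed a floor (default
8,000 bases).  Partitioning is a deterministic two-candidate majority vote —
each read's observed allele vector is compared against the two haplotype
allele vectors, ties and uninformative reads stay unassigned — followed by
consensus-refinement passes until convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .reads import AlignedRead

DEFAULT_INTERVALS: list[tuple[int, int]] = [(1000, 8000), (10000, 15000)]
DEFAULT_MIN_QUERY_LEN = 8000

HetSite = tuple[int, str, str]  # (0-based pos, allele of A, allele of B)


class PhasingImpossibleError(ValueError):
    """No heterozygous site falls inside the extraction interval."""


@dataclass
class SpanningReadSet:
    """Reads long enough to represent one fully extended amplicon."""

    interval: tuple[int, int]
    reads: list[AlignedRead]


@dataclass
class PhasedPartition:
    pool_a: list[AlignedRead]
    pool_b: list[AlignedRead]
    unassigned: list[AlignedRead]
    het_sites: list[HetSite]
    iterations: int = 1

    @property
    def pools(self) -> dict[str, list[AlignedRead]]:
        return {"A": self.pool_a, "B": self.pool_b}


def extract_spanning_reads(
    reads: Sequence[AlignedRead],
    intervals: Optional[Sequence[tuple[int, int]]] = None,
    min_query_len: int = DEFAULT_MIN_QUERY_LEN,
) -> list[SpanningReadSet]:
    """One spanning set per extraction interval (0-based half-open).

    A read belongs to a set when its reference span intersects the interval
    and its query length strictly exceeds ``min_query_len``.
    """
    if min_query_len <= 0:
        raise ValueError("min_query_len must be positive")
    intervals = list(intervals) if intervals is not None else list(DEFAULT_INTERVALS)
    sets = []
    for lo, hi in intervals:
        if lo >= hi:
            raise ValueError(f"empty interval ({lo}, {hi})")
        members = [
            r
            for r in reads
            if r.ref_start < hi and r.ref_end > lo and r.query_length > min_query_len
        ]
        sets.append(SpanningReadSet((lo, hi), members))
    return sets


def _observe(read: AlignedRead, sites: Sequence[HetSite]) -> list[Optional[str]]:
    """Observed base per het site; None when uncovered or under a D/I event."""
    obs: list[Optional[str]] = []
    for pos, _a, _b in sites:
        base, op = read.base_at(pos)
        obs.append(base if op == "M" else None)
    return obs


def _vote(obs: Sequence[Optional[str]], cand_a: Sequence[Optional[str]],
          cand_b: Sequence[Optional[str]]) -> str:
    score_a = score_b = 0
    for o, a, b in zip(obs, cand_a, cand_b):
        if o is None:
            continue  # missing observations abstain rather than count against
        if a is not None and o == a:
            score_a += 1
        if b is not None and o == b:
            score_b += 1
    if score_a > score_b:
        return "A"
    if score_b > score_a:
        return "B"
    return "-"


def _consensus(reads: list[AlignedRead], observations: dict[str, list[Optional[str]]],
               n_sites: int) -> list[Optional[str]]:
    cons: list[Optional[str]] = []
    for i in range(n_sites):
        counts: dict[str, int] = {}
        for r in reads:
            o = observations[r.read_id][i]
            if o is not None:
                counts[o] = counts.get(o, 0) + 1
        if not counts:
            cons.append(None)
            continue
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        cons.append(winners[0] if len(winners) == 1 else None)
    return cons


def phase_reads(
    spanning: SpanningReadSet,
    het_sites: Sequence[HetSite],
    max_iters: int = 10,
) -> PhasedPartition:
    """Partition spanning reads into two pools by majority vote at het sites.

    Candidate vectors start as the two haplotype allele vectors; after each
    assignment pass, every pool's per-site majority base becomes its new
    candidate vector and all reads are re-assigned, until the partition is
    stable or ``max_iters`` is reached.  Deterministic given input order.
    """
    lo, hi = spanning.interval
    sites = [s for s in het_sites if lo <= s[0] < hi]
    if not sites:
        raise PhasingImpossibleError(
            f"no heterozygous sites inside interval ({lo}, {hi})"
        )
    for pos, a, b in sites:
        if a == b:
            raise ValueError(f"het site at {pos} has identical alleles")

    observations = {r.read_id: _observe(r, sites) for r in spanning.reads}
    cand_a: list[Optional[str]] = [s[1] for s in sites]
    cand_b: list[Optional[str]] = [s[2] for s in sites]

    assignment: dict[str, str] = {}
    iterations = 0
    for iterations in range(1, max_iters + 1):
        new_assignment = {
            r.read_id: _vote(observations[r.read_id], cand_a, cand_b)
            for r in spanning.reads
        }
        if new_assignment == assignment:
            break
        assignment = new_assignment
        pool_a = [r for r in spanning.reads if assignment[r.read_id] == "A"]
        pool_b = [r for r in spanning.reads if assignment[r.read_id] == "B"]
        new_a = _consensus(pool_a, observations, len(sites)) if pool_a else cand_a
        new_b = _consensus(pool_b, observations, len(sites)) if pool_b else cand_b
        # a pool's consensus may lose a site to ties; fall back to the seed allele
        cand_a = [c if c is not None else s[1] for c, s in zip(new_a, sites)]
        cand_b = [c if c is not None else s[2] for c, s in zip(new_b, sites)]

    return PhasedPartition(
        pool_a=[r for r in spanning.reads if assignment[r.read_id] == "A"],
        pool_b=[r for r in spanning.reads if assignment[r.read_id] == "B"],
        unassigned=[r for r in spanning.reads if assignment[r.read_id] == "-"],
        het_sites=sites,
        iterations=iterations,
    )


@dataclass
class SiteReportRow:
    pos: int
    pool: str
    counts: dict[str, int]  # tracked alleles + "Other"
    percentages: dict[str, int]
    depth: int
    flagged_uncovered: bool = False


def pool_allele_report(
    partition: PhasedPartition,
    sites: Optional[Sequence[HetSite]] = None,
) -> pd.DataFrame:
    """Per-site allele counts and whole-percent shares within each pool.

    Mirrors the published per-locus count tables: for each heterozygous site
    and each pool, the two tracked alleles plus an "Other" bucket (any other
    base or a deletion), with percentages of pool depth at the site rounded
    to whole percent.  Depth-0 rows are flagged.
    """
    sites = list(sites) if sites is not None else partition.het_sites
    rows = []
    for pool_name, reads in (("A", partition.pool_a), ("B", partition.pool_b)):
        for pos, allele_a, allele_b in sites:
            counts = {allele_a: 0, allele_b: 0, "Other": 0}
            for r in reads:
                base, op = r.base_at(pos)
                if op == ".":
                    continue  # does not cover the site
                if op == "M" and base in (allele_a, allele_b):
                    counts[base] += 1
                else:
                    counts["Other"] += 1
            depth = sum(counts.values())
            pct = {
                k: (int(round(100 * v / depth)) if depth else 0)
                for k, v in counts.items()
            }
            rows.append(
                dict(
                    pos=pos, np=pos + 1, pool=pool_name,
                    **{f"count_{k}": v for k, v in counts.items()},
                    **{f"pct_{k}": v for k, v in pct.items()},
                    depth=depth, uncovered=depth == 0,
                )
            )
    return pd.DataFrame(rows)
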