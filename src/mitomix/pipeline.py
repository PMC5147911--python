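"""End-to-end pipeline: simulate → call → grid → phase → deconvolve →
reconstruct, with seeded reproducibility and a JSON run manifest.

Stage seeds are derived deterministically from the global seed, so re-running
with the same configuration reproduces byte-identical primary outputs.  The
default configuration *is* the emulated study: a 16,569 bp circular genome as
two overlapping amplicons, two same-haplogroup contributors (31 shared SNPs,
6 private SNPs + 1 private insertion each), a 1:1 mixture, a ~1000x low-error
paired-end platform and a ~300x high-error long-read platform.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as mio
from .concordance import (
    CombinedTruthSet,
    GridResult,
    combine_truth_sets,
    grid_against_fixed_truth,
    vaf_grid,
)
from .deconvolution import (
    PanelInsertion,
    PanelSNP,
    PrivateVariantPanel,
    ReadPoolAssignment,
    build_deconvolved_sets,
    deconvolve,
    export_fastq,
)
from .phasing import (
    DEFAULT_INTERVALS,
    DEFAULT_MIN_QUERY_LEN,
    HetSite,
    PhasedPartition,
    extract_spanning_reads,
    phase_reads,
    pool_allele_report,
)
from .pileup import CallSet, Pileup, build_pileup, call_snps
from .reconstruct import (
    AssemblyStats,
    ConsensusResult,
    consensus_contigs,
    coverage_summary,
    coverage_track,
    ngax_curve,
    nx_curve,
    reconstruct_contributor,
)
from .simdata import (
    ErrorProfile,
    HaplotypeSpec,
    ReferenceGenome,
    generate_haplotypes,
    generate_reference,
    simulate_long_reads,
    simulate_mixture,
    simulate_short_reads,
)


class ConfigError(ValueError):
    """Pipeline configuration failed validation."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; defaults emulate the study design."""

    # genome + haplotypes
    genome_length: int = 16569
    n_homopolymers: int = 3
    min_run: int = 6
    n_shared: int = 31
    n_private_snps_each: int = 6
    n_private_ins_each: int = 1
    contributors: tuple[str, str] = ("005", "047")
    # platforms
    short_depth: float = 1000.0
    long_depth: float = 300.0
    read_len: int = 250
    frag_mean: float = 450.0
    frag_sd: float = 50.0
    truncated_fraction: float = 0.3
    short_profile: ErrorProfile = field(default_factory=ErrorProfile.short_default)
    long_profile: ErrorProfile = field(default_factory=ErrorProfile.long_default)
    mixture_ratio: tuple[float, float] = (0.5, 0.5)
    # calling + grids
    min_depth: int = 20
    single_grid_range: tuple[float, float, float] = (0.05, 0.95, 0.05)
    mixture_grid_range: tuple[float, float, float] = (0.17, 0.53, 0.02)
    truth_vaf: float = 0.90
    mixture_truth_vaf: float = 0.25
    # phasing + reconstruction
    phasing_intervals: tuple[tuple[int, int], ...] = tuple(DEFAULT_INTERVALS)
    min_query_len: int = DEFAULT_MIN_QUERY_LEN
    reconstruction_vaf: float = 0.75
    seed: int = 1001

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ConfigError("genome_length must be >= 1000")
        if not 0 < self.truth_vaf <= 1 or not 0 < self.reconstruction_vaf <= 1:
            raise ConfigError("VAF thresholds must lie in (0, 1]")
        if abs(sum(self.mixture_ratio) - 1) > 1e-9:
            raise ConfigError("mixture_ratio must sum to 1")
        if self.frag_mean < self.read_len:
            raise ConfigError("frag_mean must be >= read_len")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("short_profile", "long_profile"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = ErrorProfile(**kwargs[key])
        for key in ("contributors", "mixture_ratio", "single_grid_range",
                    "mixture_grid_range"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        if "phasing_intervals" in kwargs:
            kwargs["phasing_intervals"] = tuple(
                tuple(iv) for iv in kwargs["phasing_intervals"]
            )
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["short_profile"] = asdict(self.short_profile)
        d["long_profile"] = asdict(self.long_profile)
        return d


@dataclass
class RunResult:
    """Everything a pipeline run computed, for programmatic inspection."""

    config: PipelineConfig
    ref: ReferenceGenome
    hap_a: HaplotypeSpec
    hap_b: HaplotypeSpec
    reads: dict
    pileups: dict[str, Pileup]
    truth_sets: dict[str, CallSet]
    single_grids: dict[str, GridResult]
    combined_truth: CombinedTruthSet
    combined_call_set: CallSet
    mixture_grid_short: GridResult
    mixture_grid_long: GridResult
    het_sites: list[HetSite]
    partitions: list[PhasedPartition]
    phased_pools: dict[str, list]
    site_report: object
    panel: PrivateVariantPanel
    assignment: ReadPoolAssignment
    deconvolved: dict[str, list]
    consensus: dict[str, ConsensusResult]
    assembly_stats: dict[str, AssemblyStats]
    metrics: dict
    manifest: dict

    @property
    def contributors(self) -> tuple[str, str]:
        return self.config.contributors


def _stage_seeds(seed: int, n: int = 12) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def phasing_accuracy(partitions, contributors) -> Optional[float]:
    """Fraction of pool-assigned long reads whose truth label matches their
    pool, over all extraction intervals (None when nothing was assigned)."""
    correct = assigned = 0
    for part in partitions:
        for pool_label, reads in (("A", part.pool_a), ("B", part.pool_b)):
            want = contributors[0] if pool_label == "A" else contributors[1]
            for r in reads:
                if r.contributor is None:
                    continue
                assigned += 1
                correct += r.contributor == want
    return correct / assigned if assigned else None


def deconvolution_purity(assignment, contributors) -> Optional[float]:
    """Fraction of privately pooled pairs carrying the correct truth label."""
    correct = routed = 0
    for pool_label, pairs in (("A", assignment.pool_a), ("B", assignment.pool_b)):
        want = contributors[0] if pool_label == "A" else contributors[1]
        for p in pairs:
            if p.contributor is None:
                continue
            routed += 1
            correct += p.contributor == want
    return correct / routed if routed else None


def detect_private_insertions(
    pileup_a: Pileup, pileup_b: Pileup, min_frac: float = 0.5, min_depth: int = 20
) -> list[PanelInsertion]:
    """Find insertion anchors supported in exactly one single-source sample.

    The majority inserted sequence at each qualifying anchor is taken; this
    recovers the private insertions from data rather than from the truth
    tables, mirroring how the private panel is established from the
    single-contributor experiments.
    """

    def anchors(pile: Pileup) -> dict[int, str]:
        depths = pile.depths
        found = {}
        for pos, bucket in pile.insertions.items():
            depth = int(depths[pos])
            if depth >= min_depth and sum(bucket.values()) / depth >= min_frac:
                found[pos] = max(sorted(bucket), key=lambda s: bucket[s])
        return found

    in_a, in_b = anchors(pileup_a), anchors(pileup_b)
    out = [PanelInsertion(p, s, "A") for p, s in in_a.items() if p not in in_b]
    out += [PanelInsertion(p, s, "B") for p, s in in_b.items() if p not in in_a]
    return sorted(out, key=lambda i: i.pos)


def het_sites_from_combined(
    combined: CombinedTruthSet, ref: ReferenceGenome, contributors
) -> list[HetSite]:
    """Heterozygous phasing sites from the combined truth set's private SNPs:
    the private carrier shows the alternate, the other the reference base."""
    sites: list[HetSite] = []
    label_a, label_b = contributors
    for pos, alt in sorted(combined.private_sites(label_a)):
        sites.append((pos, alt, ref.sequence[pos]))
    for pos, alt in sorted(combined.private_sites(label_b)):
        sites.append((pos, ref.sequence[pos], alt))
    return sorted(sites)


def run_pipeline(
    config: PipelineConfig, outdir: Optional[Path] = None, write_outputs: bool = True
) -> RunResult:
    """Execute the full analysis; optionally write all primary outputs.

    Raises :class:`StageError` naming the failing stage; outputs written
    before a failure are retained beside a ``FAILED`` marker file.
    """
    config.validate()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None and write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stages": {},
        "outputs": {},
    }
    cid_a, cid_b = config.contributors
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        ref = generate_reference(
            config.genome_length, config.n_homopolymers, config.min_run,
            seed=seeds[0],
        )
        hap_a, hap_b = generate_haplotypes(
            ref, config.n_shared, config.n_private_snps_each,
            config.n_private_ins_each, seed=seeds[1],
            contributor_ids=config.contributors,
            private_regions=list(config.phasing_intervals),
        )
        reads = {}
        for hap, s_seed, l_seed in ((hap_a, seeds[2], seeds[3]),
                                    (hap_b, seeds[4], seeds[5])):
            cid = hap.contributor_id
            reads[f"{cid}/SHORT"] = simulate_short_reads(
                ref, hap, config.short_depth, config.read_len, config.frag_mean,
                config.frag_sd, config.short_profile, seed=s_seed,
            )
            reads[f"{cid}/LONG"] = simulate_long_reads(
                ref, hap, config.long_depth, config.long_profile,
                config.truncated_fraction, seed=l_seed,
            )
        mix = simulate_mixture(
            ref, hap_a, hap_b, config.mixture_ratio,
            short_depth=config.short_depth, long_depth=config.long_depth,
            short_profile=config.short_profile, long_profile=config.long_profile,
            seed=seeds[6], read_len=config.read_len, frag_mean=config.frag_mean,
            frag_sd=config.frag_sd, truncated_fraction=config.truncated_fraction,
        )
        reads["mixture/SHORT"] = mix["SHORT"]
        reads["mixture/LONG"] = mix["LONG"]
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 2)}

        stage = "call"
        t0 = time.perf_counter()
        pileups = {key: build_pileup(rs, ref) for key, rs in reads.items()}
        truth_sets = {
            cid: call_snps(
                pileups[f"{cid}/SHORT"], ref, config.truth_vaf,
                min_depth=config.min_depth, ploidy_mode="single_source",
                platform=f"{cid}/SHORT",
            )
            for cid in config.contributors
        }
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 2)}

        stage = "grid"
        t0 = time.perf_counter()
        single_grids = {
            cid: vaf_grid(
                pileups[f"{cid}/LONG"], pileups[f"{cid}/SHORT"], ref,
                test_range=config.single_grid_range,
                truth_range=config.single_grid_range,
                mode="single_source", min_depth=config.min_depth,
            )
            for cid in config.contributors
        }
        combined = combine_truth_sets(
            truth_sets[cid_a], truth_sets[cid_b], cid_a, cid_b
        )
        combined_call_set = combined.as_call_set(
            truth_sets[cid_a], truth_sets[cid_b]
        )
        mixture_grid_short = grid_against_fixed_truth(
            pileups["mixture/SHORT"], combined_call_set, ref,
            config.mixture_grid_range, mode="mixture", min_depth=config.min_depth,
        )
        mixture_truth = call_snps(
            pileups["mixture/SHORT"], ref, config.mixture_truth_vaf,
            min_depth=config.min_depth, ploidy_mode="mixture",
            platform="mixture/SHORT",
        )
        mixture_grid_long = grid_against_fixed_truth(
            pileups["mixture/LONG"], mixture_truth, ref,
            config.mixture_grid_range, mode="mixture", min_depth=config.min_depth,
        )
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 2)}

        stage = "phase"
        t0 = time.perf_counter()
        het_sites = het_sites_from_combined(combined, ref, config.contributors)
        spanning = extract_spanning_reads(
            reads["mixture/LONG"], config.phasing_intervals, config.min_query_len
        )
        partitions = [
            phase_reads(s, het_sites) for s in spanning if any(
                lo <= h[0] < hi for h in het_sites for lo, hi in [s.interval]
            )
        ]
        phased_pools = {cid_a: [], cid_b: []}
        for part in partitions:
            phased_pools[cid_a].extend(part.pool_a)
            phased_pools[cid_b].extend(part.pool_b)
        import pandas as pd

        site_report = pd.concat(
            [pool_allele_report(p) for p in partitions], ignore_index=True
        ) if partitions else pd.DataFrame()
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 2)}

        stage = "deconvolve"
        t0 = time.perf_counter()
        panel_snps = [
            PanelSNP(pos, a, b)
            for pos, a, b in het_sites
        ]
        panel_ins = detect_private_insertions(
            pileups[f"{cid_a}/SHORT"], pileups[f"{cid_b}/SHORT"],
            min_depth=config.min_depth,
        )
        panel = PrivateVariantPanel(panel_snps, panel_ins)
        assignment = deconvolve(reads["mixture/SHORT"], panel)
        set_a, set_b = build_deconvolved_sets(assignment)
        deconvolved = {cid_a: set_a, cid_b: set_b}
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 2)}

        stage = "reconstruct"
        t0 = time.perf_counter()
        consensus = {}
        assembly_stats = {}
        for cid, hap in ((cid_a, hap_a), (cid_b, hap_b)):
            result = reconstruct_contributor(
                phased_pools[cid], deconvolved[cid], ref,
                vaf=config.reconstruction_vaf, contributor_id=cid, truth=hap,
            )
            consensus[cid] = result
            contigs = consensus_contigs(result)
            assembly_stats[cid] = ngax_curve(contigs, len(ref))
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 2)}

        metrics = {
            "single_source_max_f1": {
                cid: single_grids[cid].max_f1 for cid in config.contributors
            },
            "single_source_argmax": {
                cid: single_grids[cid].argmax_cells[:4]
                for cid in config.contributors
            },
            "combined_truth": {
                "shared": combined.n_shared, "private": combined.n_private,
            },
            "mixture_short_max_f1": mixture_grid_short.max_f1,
            "mixture_long_max_f1": mixture_grid_long.max_f1,
            "phasing_accuracy": phasing_accuracy(partitions, config.contributors),
            "deconvolution_purity": deconvolution_purity(
                assignment, config.contributors
            ),
            "consensus": {
                cid: {"tp": consensus[cid].tp, "fp": consensus[cid].fp,
                      "fn": consensus[cid].fn}
                for cid in config.contributors
            },
            "n50": {cid: assembly_stats[cid].n50 for cid in config.contributors},
            "nga50": {cid: assembly_stats[cid].nga50 for cid in config.contributors},
        }
        manifest["metrics"] = metrics
        manifest["rotation"] = ref.rotation
        manifest["amplicons"] = [
            {"name": a.name, "start": a.start, "end": a.end} for a in ref.amplicons
        ]

        if outdir is not None and write_outputs:
            _write_outputs(
                outdir, manifest, ref, (hap_a, hap_b), reads, pileups,
                single_grids, mixture_grid_short, mixture_grid_long, het_sites,
                panel, phased_pools, site_report, deconvolved, consensus,
                assembly_stats, config,
            )
    except Exception as exc:  # noqa: BLE001 — re-raised with the stage name
        if outdir is not None and write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc

    return RunResult(
        config=config, ref=ref, hap_a=hap_a, hap_b=hap_b, reads=reads,
        pileups=pileups, truth_sets=truth_sets, single_grids=single_grids,
        combined_truth=combined, combined_call_set=combined_call_set,
        mixture_grid_short=mixture_grid_short, mixture_grid_long=mixture_grid_long,
        het_sites=het_sites, partitions=partitions, phased_pools=phased_pools,
        site_report=site_report, panel=panel, assignment=assignment,
        deconvolved=deconvolved, consensus=consensus,
        assembly_stats=assembly_stats, metrics=metrics, manifest=manifest,
    )


def _write_outputs(
    outdir: Path, manifest, ref, haps, reads, pileups, single_grids,
    mixture_grid_short, mixture_grid_long, het_sites, panel, phased_pools,
    site_report, deconvolved, consensus, assembly_stats, config,
) -> None:
    mio.write_fasta(ref, outdir / "reference.fasta")
    mio.write_truth_table(list(haps), ref, outdir / "truth_variants.tsv")
    for key, rs in reads.items():
        name = key.replace("/", "_").lower()
        mio.write_sam(rs, ref, outdir / f"{name}.sam")
    for key, pile in pileups.items():
        name = key.replace("/", "_").lower()
        depth = pile.depths
        mio.write_bedgraph(depth, ref, outdir / f"{name}.depth.bedgraph")
    for cid, grid in single_grids.items():
        grid.to_long().to_csv(outdir / f"grid_single_{cid}.tsv", sep="\t", index=False)
        grid.f1_matrix().to_csv(outdir / f"grid_single_{cid}.matrix.tsv", sep="\t")
    mixture_grid_short.to_long().to_csv(
        outdir / "grid_mixture_short.tsv", sep="\t", index=False
    )
    mixture_grid_long.to_long().to_csv(
        outdir / "grid_mixture_long.tsv", sep="\t", index=False
    )
    # per-site concordance track at the best long-vs-short mixture cell
    best_j = max(
        range(len(mixture_grid_long.test_thresholds)),
        key=lambda j: (
            mixture_grid_long.cells[0][j].f1
            if mixture_grid_long.cells[0][j].f1 is not None
            else -1.0
        ),
    )
    mio.write_concordance_bed(
        mixture_grid_long.cells[0][best_j], ref,
        outdir / "mixture_long_concordance.bed",
    )
    mio.write_het_sites(het_sites, outdir / "het_sites.tsv")
    mio.write_panel(panel, outdir / "private_panel.tsv")
    for cid, pool in phased_pools.items():
        mio.write_sam(pool, ref, outdir / f"phased_{cid}.sam")
    if len(site_report):
        site_report.to_csv(outdir / "phased_site_report.tsv", sep="\t", index=False)
    for cid, pairs in deconvolved.items():
        mio.write_sam(pairs, ref, outdir / f"deconvolved_{cid}.sam")
        export_fastq(
            pairs,
            outdir / f"deconvolved_{cid}_R1.fastq",
            outdir / f"deconvolved_{cid}_R2.fastq",
        )
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(result.sequence), id=f"consensus_{cid}", description="")
        for cid, result in consensus.items()
    ]
    SeqIO.write(records, str(outdir / "consensus.fasta"), "fasta")
    stats_obj = {
        cid: {
            "contigs": st.contig_lengths, "total": st.total_length,
            "n50": st.n50, "nga50": st.nga50,
            "nx": st.nx, "ngax": st.ngax,
        }
        for cid, st in assembly_stats.items()
    }
    mio.write_json(stats_obj, outdir / "assembly_stats.json")
    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _digest(path)
    mio.write_json(manifest, outdir / "manifest.json")
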