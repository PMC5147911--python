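"""Rebuild each contributor's genome from a mixture and score the assembly.

Runs the whole pipeline at reduced depth, then shows the reconstruction
stage: phased long reads + deconvolved short reads are pooled, every variant
signal reaching VAF 0.75 is applied to the reference, and the supporting
call set is compared with the contributor's truth variants.  Nx/NGAx curves
summarise the consensus contigs.
"""

from mitomix.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(short_depth=200, long_depth=100, seed=11)
run = run_pipeline(config, write_outputs=False)

for cid in run.contributors:
    result = run.consensus[cid]
    stats = run.assembly_stats[cid]
    truth = run.hap_a if cid == run.contributors[0] else run.hap_b
    print(f"contributor {cid}:")
    print(f"  consensus length {len(result.sequence)} bp "
          f"({len(result.gaps)} gaps)")
    print(f"  supporting calls at VAF>=0.75: {len(result.supporting_calls)} "
          f"(truth {len(truth.all_variants)}) -> "
          f"TP={result.tp} FP={result.fp} FN={result.fn}")
    print(f"  contigs {stats.contig_lengths}, N50={stats.n50}, "
          f"NGA50={stats.nga50}")

print(f"\npipeline metrics: phasing accuracy "
      f"{100 * run.metrics['phasing_accuracy']:.1f}%, deconvolution purity "
      f"{100 * run.metrics['deconvolution_purity']:.2f}%")
print("\nTP equal to the truth count with zero FP/FN means the consensus is"
      "\n100% concordant with the contributor's variant profile at VAF 0.75.")
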