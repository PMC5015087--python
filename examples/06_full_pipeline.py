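"""The whole study at desk scale: simulate -> call -> rank -> compare -> enrich.

Generates the default synthetic two-condition scenario (two 5 Mb
chromosomes, six megabase-scale islands, 30 planted super-enhancers,
island genes downregulated after knock-down), runs every stage, and
prints the recovery of the planted truth.
"""

import numpy as np

from epidomains import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=7, n_perm=200))
report = result.report

print(f"top islands: {len(result.top_islands)} "
      f"(planted {len(result.bundle.islands)})")
print(f"island recovery (bp Jaccard):   {report['island_jaccard']:.4f}")
print(f"SE label accuracy:              {report['se_label_accuracy']:.2%}")
print(f"signature precision / recall:   {report['signature_precision']:.2%} / "
      f"{report['signature_recall']:.2%}")
for cls in ("intergenic", "LADs", "CDS_K36me3", "K27ac_enhancers"):
    fc = report["feature_log2fc"][cls]
    print(f"median log2fc {cls:16s} {fc['median_log2fc']:+.3f} "
          f"(planted {fc['planted']:+.1f})")
planted = result.gsea_results["ISLAND_SIGNATURE"]
print(f"planted signature GSEA: es={planted.es:+.3f} fdr={planted.fdr_q:.4f}")
# Island boundaries are recovered to within a window or two (Jaccard ~1),
# every super-enhancer lands in its planted ratio band, the intergenic
# feature class loses ~half its signal (log2fc ~ -1) while protected CDS
# segments hold at ~0, and the island gene set is significantly depleted
# in the knock-down ranking.
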