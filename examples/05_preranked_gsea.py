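"""Preranked GSEA of a knock-down expression contrast.

Builds an expression table where the members of one gene set are pushed
to the bottom of the ranking (downregulated), runs the weighted-KS
enrichment with a gene-set permutation null, and prints ES / NES /
nominal p / FDR q and the leading edge.
"""

import numpy as np
import pandas as pd

from epidomains import gsea_preranked, rank_genes

rng = np.random.default_rng(7)
n = 100
stats = rng.normal(0, 1, n)
members = [f"g{i}" for i in range(0, 100, 10)]  # every 10th gene
for i in range(0, 100, 10):
    stats[i] -= 3.0  # planted downregulation

table = pd.DataFrame(
    {
        "gene_id": [f"g{i}" for i in range(n)],
        "fpkm_a": 1.0,
        "fpkm_b": 2.0,
        "log2fc": stats * 0.3,
        "stat": stats,
        "fdr": 0.5,
    }
)

ranked = rank_genes(table)
sets = {"PLANTED_DOWN": members, "RANDOM": [f"g{i}" for i in range(5, 100, 17)]}
results = gsea_preranked(ranked, sets, n_perm=1000, seed=7)

for name, r in results.items():
    print(
        f"{name:13s} size={r.set_size:2d}  es={r.es:+.3f}  nes={r.nes:+.3f}  "
        f"p={r.nominal_p:.4f}  fdr={r.fdr_q:.4f}  leading_edge={len(r.leading_edge)}"
    )
# The planted set gets a strongly negative ES with FDR ~ 0 (its members
# cluster at the bottom of the ranking); the random set does not.
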