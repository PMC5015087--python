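"""Map islands to genes through +/-5 kb promoter windows.

Places genes in and around one island, builds the promoter windows,
extracts the island-embedded gene signature (any >=1 bp promoter
overlap), and assigns a regulatory region to its nearest TSS.
"""

from epidomains import (
    GeneAnnotation,
    Genome,
    Interval,
    genes_in_islands,
    nearest_gene,
    promoters,
)

genome = Genome({"chr1": 1_000_000})
island = Interval("chr1", 300_000, 500_000)

genes = [
    GeneAnnotation("inside_plus", "chr1", "+", 350_000, 360_000),
    GeneAnnotation("inside_minus", "chr1", "-", 390_000, 400_000),
    GeneAnnotation("edge_4kb_out", "chr1", "+", 504_000, 512_000),   # promoter straddles
    GeneAnnotation("far_away", "chr1", "+", 800_000, 810_000),
]

proms = promoters(genes, genome, flank=5_000)
signature = genes_in_islands([island], proms)
print("island-embedded signature:", sorted(signature))

assigned = nearest_gene([Interval("chr1", 520_000, 530_000)], genes)
print("nearest gene to chr1:520000-530000:", assigned[0])
# 'edge_4kb_out' joins the signature because its promoter window reaches
# 1 kb into the island even though the TSS sits outside; the regulatory
# region maps to the gene with the closest TSS (edge_4kb_out, 8 kb away).
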