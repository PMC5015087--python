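# epidomains

Analysis toolkit for **megabase-scale broad histone-mark domains** in
two-condition ChIP-seq studies, built around the question of how an
overexpressed H3K36 methyltransferase (NSD2) spreads H3K36me2 into
intergenic and lamina-associated chromatin, and what happens to the genes
embedded in those domains when the enzyme is depleted. It is a library for
computational epigenomics: each analysis stage is an importable function,
with narrative scripts in `examples/` and a thin `epidomains` CLI for
shell use.

## What it computes

- **Island calling** (`epidomains.islands`) — a window/gap caller for broad
  marks: fragment midpoints are counted in non-overlapping windows of
  *W* = 200 bp; a window with count *c* is eligible when
  P(X ≥ c | Poisson λ₀) ≤ 0.2, with λ₀ the genome-wide expected count per
  window; eligible runs separated by ≤ 600 bp of ineligible windows merge
  into islands, each scored Σ −ln P(cᵢ; λ₀) over its eligible windows and
  kept at Benjamini–Hochberg *q* ≤ 0.01 on its Poisson upper-tail p-value.
  Defaults: window 200, gap 600, modelled fragment length 260, FDR 0.01.
- **Rank ordering with the elbow cutoff** (`epidomains.rose`) — called
  intervals within 12.5 kb are stitched; stitched regions are ranked by
  (optionally input-subtracted) signal; on the ascending curve rescaled to
  the unit square the cutoff is argmaxᵢ (xᵢ − yᵢ), the slope-1 tangent
  point for convex curves. Regions above the cutoff are the top set —
  super-enhancers for H3K27ac, top islands for H3K36me2.
- **Differential domains** (`epidomains.differential`) — library-normalized
  subtraction tracks (per-bin a/Nₐ − b/N_b); classification of merged
  super-enhancers by cross-sample density ratio (> 10× acquired, 0.5–2×
  shared); per-feature-class log₂ fold changes with a paired t-test;
  selection of islands losing signal after knock-down; smoothed
  chromosome-scale log₂-ratio profiles; CpG/gene composition per kb.
- **Gene mapping** (`epidomains.genes`) — strand-aware ±5 kb promoter
  windows, island-embedded gene signatures (≥ 1 bp promoter overlap),
  nearest-TSS assignment, promoter enrichment at island boundaries, and
  metagene profiles over scaled region bodies.
- **Preranked GSEA** (`epidomains.gsea`) — weighted-KS enrichment score
  (hit steps ∝ |stat|ᵖ, p = 1), gene-set permutation null (default 1000
  permutations), NES, nominal p, sign-stratified FDR and leading edge;
  plus hypergeometric overlap tests and composite-signature compilation
  from downregulated set members (FDR < 0.05).
- **Synthetic studies** (`epidomains.simulate`) — a seeded generator that
  plants the full study structure (islands with retained/losing internal
  segments, acquired/shared super-enhancers, biased gene placement,
  downregulated island genes) and records the truth, so every stage can be
  scored against a known answer without any downloads.

## Worked example

`python examples/06_full_pipeline.py` simulates the default scenario (two
5 Mb chromosomes, six planted islands of 0.2–1 Mb at 30 fragments/kb over
a 3 fragments/kb background, 30 super-enhancers, 130 genes) and runs every
stage:

```
top islands: 6 (planted 6)
island recovery (bp Jaccard):   0.9992
SE label accuracy:              100.00%
signature precision / recall:   100.00% / 100.00%
median log2fc intergenic       -1.010 (planted -1.0)
median log2fc LADs             -0.979 (planted -1.0)
median log2fc CDS_K36me3       -0.086 (planted +0.0)
median log2fc K27ac_enhancers  -0.001 (planted +0.0)
planted signature GSEA: es=-1.000 fdr=0.0000
```

Reading: all six planted megabase islands are recovered almost to the
base pair and sit above the rank-curve elbow; every super-enhancer lands
in its planted ratio band; inside the islands the intergenic and LAD
segments lose half their signal after knock-down (log₂ fc ≈ −1) while
H3K27ac- and H3K36me3-protected segments hold at ≈ 0; and the genes whose
promoters lie in the losing islands form a signature that preranked GSEA
finds maximally depleted (ES = −1) in the knock-down expression ranking.

The same run from the shell:

```bash
epidomains run --seed 7 --out runs/demo/
```

Other entry points: `epidomains simulate`, `call-islands`, `rose`, `gsea`
(see `epidomains --help`), and one example script per capability in
`examples/`.

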