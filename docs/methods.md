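# Methods

This note documents the statistical models, default parameters, numerical
choices and known limitations of the package. Nothing here states an
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Coordinate model and tracks

All intervals are 0-based half-open (BED convention); BED is the
interchange format for intervals and read positions, bedGraph for tracks.
A `CoverageTrack` stores one value per `bin_size` bp; a raw track holds
the number of extended fragments overlapping each bin (exact per-base
coverage at `bin_size` 1), a normalized track is scaled to
fragments-per-million (FPM). Region sums treat a bin's value as a uniform
per-base level inside the bin, so partial bins contribute pro rata; at
`bin_size` 1 every region statistic is exact. Reads are modelled as
fragments anchored at their 5′ end and extended in the strand direction to
the modelled fragment length (default 260 bp, clipped at chromosome
ends) — the simplest model consistent with a fragment-size parameter.
The pipeline default `bin_size` is 50 bp, a compromise between memory and
boundary resolution (top islands span hundreds of kb, so a ≤ 50 bp
quantization error is negligible).

## Island caller

Broad-mark enrichment is detected with a window/gap scheme. Fragment
midpoints (5′ end shifted by half the fragment length in strand direction)
are counted in non-overlapping windows of `window_size` W (default
200 bp); assigning each fragment to exactly one window avoids double
counting. The background is a single genome-wide Poisson rate

    λ₀ = total_fragments × W / (genome_length × effective_genome_fraction),

window *i* is *eligible* when the upper tail P(X ≥ cᵢ | λ₀) ≤ `window_p`
(default 0.2), and maximal runs of eligible windows merge across gaps of
at most `gap_size` / W ineligible windows (default 600 bp / 200 bp = 3).
An island's score is Σ −ln pmf(cᵢ; λ₀) over its eligible windows; its
p-value is the Poisson upper tail of its total count against λ₀ ×
n_windows (or, with a control track, the library-size-scaled control
count plus a pseudocount of 1); q-values are Benjamini–Hochberg over all
candidates and islands are kept at q ≤ `fdr_threshold` (default 0.01).

This per-window-eligibility + per-island-Poisson + BH construction is a
deliberate reconstruction of the published window/gap callers from their
four printed parameters; it does not reproduce any specific tool's
aggregation-probability (E-value) machinery, and no attempt is made to
match such tools numerically. `effective_genome_fraction` defaults to
0.74 (the conventional mappable fraction for the human reference); fully
synthetic genomes use 1.0.

## Rank ordering and the elbow

Called intervals within `stitch_distance` (12.5 kb) are stitched
transitively; the gap between two intervals merges them when it is ≤ the
distance, so bookended and overlapping intervals always merge. Stitched
regions are scored by their signal, Σ per-base (chip − input) over the
region in FPM·bp, floored at 0 (without an input track, the chip sum
alone). On the ascending signal curve rescaled to the unit square
(xᵢ = i/(N−1), yᵢ = sᵢ/s_max) the cutoff index is argmax(xᵢ − yᵢ), with
ties broken toward larger i — i.e. toward *fewer* top regions, the
conservative direction. For a convex curve this is exactly the point
where a line of slope 1 is tangent to the curve. A region is "top" when
its signal is strictly above the cutoff signal; if all signals are equal
the top set is empty, and an all-zero vector is an error. The identical
procedure serves two configurations: H3K27ac intervals → super-enhancers,
H3K36me2 intervals → top islands. No promoter-exclusion window is applied.

## Differential layer

The subtraction track is per-bin a/Nₐ − b/N_b on a shared grid (read
fractions; multiply by 10⁶ for FPM). Merged super-enhancer regions (union
of both samples' top sets, overlap or bookended → one region) are labelled
by the ratio of per-bp FPM densities with a pseudocount ε = 0.01 FPM:
acquired if ratio > 10, shared if 0.5 ≤ ratio ≤ 2, other otherwise — the
labels partition the regions. Per-bp density makes the ratio independent
of region length. Feature-class fold changes are per-feature
log₂((d_dox + ε)/(d_veh + ε)) of mean FPM densities, with a paired
two-tailed t-test per class (undefined, reported as NaN, for < 2 features
or a constant difference). "Losing" islands are those with whole-island
log₂ fc ≤ `loss_threshold`; the threshold is not printed anywhere in the
source material, so it defaults to −0.5 (half a doubling) and is echoed
in the run manifest. Chromosome-scale profiles re-bin both tracks to
100 kb, take the pseudocounted log₂ FPM ratio and smooth with a centered
11-bin running mean (edges use the available window); both knobs are
configurable since only "smoothed" is specified upstream. Composition
statistics count CpG-island midpoints and gene TSSs per kb of region.

## Gene mapping

Promoter windows are [TSS − 5 kb, TSS + 5 kb), strand-aware (TSS =
tx_start on +, tx_end on −), clipped at chromosome bounds. A gene joins
an island signature when its promoter overlaps any island by ≥ 1 bp; the
stricter full-containment reading is available via
`require_containment=True`. Regulatory regions map to the gene with the
nearest TSS (distance 0 inside the region, ties to the lexicographically
smaller gene id); this deliberately replaces regulatory-domain machinery
with the transparent nearest-single-TSS rule.

**Boundary enrichment.** The boundary zone is the first and last
`boundary_width` (default 10 kb) of each island longer than twice that
width. Each island-resident promoter is assigned by its center (the TSS)
to the boundary zone or the interior, and the boundary count is tested
against Binomial(n, p = boundary bp / island bp) with a two-sided mid-p.
Two choices here are deliberate: counting promoters by their center
rather than by interval overlap keeps the success probability exactly the
bp fraction (a 10 kb window straddling a zone edge would otherwise count
toward both zones and break the null), and mid-p keeps the discrete
null's p-values close to uniform, which the calibration test verifies by
simulation (1000 seeded draws of uniformly placed promoters,
Kolmogorov–Smirnov test against the uniform distribution; the simulation
uses 2000 promoters per draw so that the binomial's discreteness steps
are small relative to the KS resolution).

**Metagene profiles** split each region body into n equal spans
(5′→3′ for stranded regions) plus fixed-width flanks, average per-base
density per span, and average across regions with equal weight; regions
shorter than the bin count are skipped and counted.

## Preranked enrichment

Genes are ranked by the expression test statistic, descending, ties
broken lexicographically (recorded, deterministic). The enrichment score
of a set is the signed extremum of the running sum with hit steps
|statᵢ|ᵖ / Σ_hits |stat|ᵖ and miss steps 1/(N − N_hits); the weight p
defaults to 1 (the common tool default; the upstream description does not
state it). Degenerate cases: a set equal to the universe gets ES = 1 with
a warning (no miss steps exist); all-zero hit weights fall back to equal
steps. The null is "gene set" permutation: ES of random same-size subsets
of the ranked universe (`n_perm` default 1000); tiny universes can be
enumerated exhaustively, making the nominal p exact. NES divides ES by
the mean |null ES| of matching sign; nominal p is
(1 + #{same-sign null at least as extreme})/(n_perm + 1) (the exact
fraction in exhaustive mode); FDR q compares each NES against the pooled
sign-matched normalized null across all sets divided by the fraction of
observed NES at least as extreme, capped at 1. Composite signatures take
the union of the input sets intersected with genes having log₂ fc < 0 and
FDR below the threshold (default 0.05) in at least one expression table —
"significantly downregulated" requires both conditions. Overlaps between
gene lists use the hypergeometric upper tail P(X ≥ k).

Expression tables are consumed, never fitted: genes with FPKM < 0.05 in
both conditions are dropped before ranking, all other rows kept.

## Synthetic scenario

The generator emulates the study's structure at desk scale so that every
stage has a known answer. Defaults (the study conditions):

- genome: 2 chromosomes × 5 Mb; 6 planted islands of 0.2–1 Mb.
- H3K36me2: 30 fragments/kb inside islands, 3/kb background. In the
  knock-down condition, island segments marked by H3K27ac (enhancers,
  active TSSs) or by H3K36me3 (covered CDS) retain the island density;
  everything else in the island (intergenic, LADs, unprotected CDS) is
  multiplied by the loss fraction 0.5 → planted log₂ fc = −1 for losing
  classes, 0 for retained ones.
- The ChIP mass lost from islands reappears at 30 enhancer regions
  outside the islands (the post-knock-down redistribution toward
  acetylated regions), so both libraries have equal expected size and an
  FPM comparison measures the planted fold changes without a
  composition bias — without this, normalization would shift every log₂
  fc by log₂(N_veh/N_dox) ≈ +0.5 and the planted values would be
  unrecoverable by construction.
- 100 minor H3K36me2 regions (2–10 kb at 20/kb, retained in both
  conditions) play the role of ordinary transcribed-gene-body enrichment:
  they give the rank curve its tail, so the elbow has something to cut.
  Likewise 150 typical enhancers (1.5 kb at 25/kb, shared) form the tail
  for the H3K27ac rankings.
- 30 super-enhancers of 40 kb, 10 per class, with per-kb densities
  (sample a, sample b) of (50, 1) acquired, (25, 25) shared, (1, 25)
  other, over a 1/kb background — comfortably inside the >10× / 0.5–2×
  ratio bands after FPM normalization.
- 130 genes placed with a 3.5× density bias away from islands, plus 10
  unexpressed genes (FPKM < 0.05 in both conditions) exercising the
  expression filter; CpG islands are twice as dense outside islands.
- Island-embedded genes get log₂ fc ~ N(−1, 0.3) in the knock-down,
  background genes N(0, 0.3); the test statistic is fc/σ and FDRs are
  BH-adjusted normal p-values — the pipeline consumes, never produces,
  differential-expression statistics.
- Fragment counts are Poisson per planted segment with uniform placement
  (matching the caller's background model, so parameter recovery is
  well-posed); all randomness flows from one seed through a fixed
  generator-spawn hierarchy, and the planted truth is recorded in a JSON
  manifest.

`depth_scale` multiplies every ChIP density uniformly; the
sequencing-scale acceptance run uses 8.0 (~1M fragments per H3K36me2
track on the 10 Mb genome). What passing these tests shows is that the
implementation recovers its own generative model at realistic depths; the
generator does not model mappability, GC bias, fragment-length variation
or replicate structure, so recovery rates on real data will be lower.

## Determinism and problem sizes

Pipeline reruns with the same config and seed are byte-identical: all
randomness is seeded, no timestamps enter output files (stage timings go
to stderr only), and floats are written with fixed formatting. Test and
acceptance problem sizes — toy genomes of ≤ 100 windows for oracle
equivalence, 1000 random vectors for the elbow, 500 instances for
stitching, the default and ×8-depth scenarios for end-to-end recovery —
were chosen to make each check statistically meaningful at interactive
runtimes.

## Known limitations

- The island caller is a principled reconstruction, not a numeric clone
  of any published tool; scores and q-values are comparable in meaning
  but not in value.
- The genome-wide Poisson background overestimates the local background
  when strong domains occupy a large genome fraction, which makes the
  caller conservative for moderate enrichment in such regimes.
- BAM input is out of scope; read positions arrive as BED (convert with
  `bedtools bamtobed`). BigWig output is likewise out of scope; tracks
  are bedGraph.
- The boundary-enrichment statistic is one defensible construction of a
  test that is not fully specified upstream; its output records the
  boundary width used.
- GSEA implements gene-set permutation only (the appropriate null for
  preranked input), not phenotype permutation.
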