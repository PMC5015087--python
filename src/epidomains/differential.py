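"""Two-condition domain comparisons.

Covers the comparative layer of the analysis: library-size-normalized
subtraction tracks (treatment minus vehicle), classification of merged
super-enhancers into cancer-acquired / shared / other by their H3K27ac
density ratio, per-feature-class log2 fold changes of domain signal with a
paired t-test, selection of islands that lose signal after knock-down,
smoothed chromosome-scale ratio profiles, and island composition statistics
(CpG islands and genes per kb).

Ratio conventions: densities are fragments-per-million per bp; every ratio
and log2 uses a pseudocount (default 0.01 FPM) so ratios are finite when a
region is empty in one condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CoverageTrack, GeneAnnotation, Genome, Interval
from .islands import Island
from .rose import StitchedRegion

__all__ = [
    "PSEUDOCOUNT_FPM",
    "SEClassification",
    "FeatureClassChange",
    "CompositionStats",
    "subtraction_track",
    "merge_intervals",
    "classify_superenhancers",
    "feature_log2fc",
    "losing_islands",
    "smoothed_ratio_profile",
    "composition_stats",
]

PSEUDOCOUNT_FPM = 0.01


@dataclass(frozen=True)
class SEClassification:
    """A merged super-enhancer region labelled by its cross-sample density ratio.

    acquired: density ratio (sample a vs b) > 10; shared: ratio in [0.5, 2];
    anything else: other.
    """

    region: Interval
    density_a: float
    density_b: float
    ratio: float
    label: str


@dataclass(frozen=True)
class FeatureClassChange:
    """Per-feature log2 fold changes for one genomic feature class."""

    class_name: str
    log2fc: np.ndarray
    paired_t_p: float  # NaN when undefined (<2 features or zero variance)
    n_features: int


@dataclass(frozen=True)
class CompositionStats:
    cpg_per_kb: float
    genes_per_kb: float
    total_kb: float
    n_cpg: int
    n_genes: int


def subtraction_track(track_a: CoverageTrack, track_b: CoverageTrack) -> CoverageTrack:
    """Per-bin difference of read fractions: a/total_a - b/total_b.

    Both tracks must be raw counts on the same genome and bin grid. The
    result is normalized (may be negative) and records both library sizes.
    """
    if not track_a.same_grid(track_b):
        raise ValueError("tracks are on different genomes or bin grids")
    if track_a.total_fragments <= 0 or track_b.total_fragments <= 0:
        raise ValueError("both tracks need a positive fragment total")
    values = {
        c: track_a.values[c] / track_a.total_fragments
        - track_b.values[c] / track_b.total_fragments
        for c in track_a.genome
    }
    return CoverageTrack(
        track_a.genome,
        track_a.bin_size,
        values,
        total_fragments=0,
        normalized=True,
        metadata={
            "total_a": track_a.total_fragments,
            "total_b": track_b.total_fragments,
        },
    )


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals: overlapping or bookended intervals become one region."""
    out: list[Interval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            out[-1] = Interval(prev.chrom, prev.start, max(prev.end, iv.end))
        else:
            out.append(Interval(iv.chrom, iv.start, iv.end))
    return out


def _label(ratio: float) -> str:
    if ratio > 10:
        return "acquired"
    if 0.5 <= ratio <= 2:
        return "shared"
    return "other"


def classify_superenhancers(
    se_a: Sequence[Interval | StitchedRegion],
    se_b: Sequence[Interval | StitchedRegion],
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    pseudocount: float = PSEUDOCOUNT_FPM,
) -> list[SEClassification]:
    """Merge both samples' super-enhancer sets and label each merged region.

    Densities are per-bp FPM in each sample over the merged region; the
    ratio is pseudocount-stabilized. Labels partition the regions into
    acquired (> 10x), shared (0.5x-2x) and other.
    """
    if not track_a.normalized or not track_b.normalized:
        raise ValueError("classification expects FPM-normalized tracks")
    merged = merge_intervals(
        [Interval(r.chrom, r.start, r.end) for r in [*se_a, *se_b]]
    )
    out = []
    for region in merged:
        da = track_a.region_density(region.chrom, region.start, region.end)
        db = track_b.region_density(region.chrom, region.start, region.end)
        ratio = (da + pseudocount) / (db + pseudocount)
        out.append(SEClassification(region, da, db, ratio, _label(ratio)))
    return out


def feature_log2fc(
    track_dox: CoverageTrack,
    track_veh: CoverageTrack,
    features_by_class: dict[str, Sequence[Interval]],
    pseudocount: float = PSEUDOCOUNT_FPM,
) -> dict[str, FeatureClassChange]:
    """Per-feature signal log2 fold change (dox vs vehicle), by feature class.

    For each feature interval the mean FPM density is computed in both
    conditions; the class-level paired two-tailed t-test compares the
    per-feature density pairs. Classes with fewer than 2 features, or a
    constant difference, get paired_t_p = NaN.
    """
    if not track_dox.normalized or not track_veh.normalized:
        raise ValueError("feature fold changes expect FPM-normalized tracks")
    out: dict[str, FeatureClassChange] = {}
    for name, feats in features_by_class.items():
        dens_d = np.array(
            [track_dox.region_density(f.chrom, f.start, f.end) for f in feats]
        )
        dens_v = np.array(
            [track_veh.region_density(f.chrom, f.start, f.end) for f in feats]
        )
        lfc = np.log2((dens_d + pseudocount) / (dens_v + pseudocount))
        if len(feats) >= 2 and np.ptp(dens_d - dens_v) > 0:
            p = float(stats.ttest_rel(dens_d, dens_v).pvalue)
        else:
            p = float("nan")
        out[name] = FeatureClassChange(name, lfc, p, len(feats))
    return out


def losing_islands(
    top_islands: Sequence[Island | StitchedRegion | Interval],
    track_dox: CoverageTrack,
    track_veh: CoverageTrack,
    loss_threshold: float = -0.5,
    pseudocount: float = PSEUDOCOUNT_FPM,
) -> list:
    """Islands whose whole-island log2 fold change (dox vs vehicle) <= threshold."""
    out = []
    for isl in top_islands:
        dd = track_dox.region_density(isl.chrom, isl.start, isl.end)
        dv = track_veh.region_density(isl.chrom, isl.start, isl.end)
        if np.log2((dd + pseudocount) / (dv + pseudocount)) <= loss_threshold:
            out.append(isl)
    return out


def smoothed_ratio_profile(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    bin_size: int = 100_000,
    smooth_bins: int = 11,
    genes: Sequence[GeneAnnotation] | None = None,
    expression: pd.DataFrame | None = None,
    pseudocount: float = PSEUDOCOUNT_FPM,
) -> dict[str, pd.DataFrame]:
    """Chromosome-scale smoothed log2 signal ratio, with an optional expression companion.

    Tracks are re-binned to ``bin_size`` (summing raw counts), converted to
    FPM, and the per-bin log2 ratio is smoothed with a centered running mean
    of ``smooth_bins`` bins (edges averaged over the available window). When
    genes + expression are given, each bin also carries the mean expression
    log2fc of genes whose TSS falls in the bin.
    """
    if smooth_bins % 2 != 1 or smooth_bins < 1:
        raise ValueError("smooth_bins must be odd and positive")
    if not track_a.same_grid(track_b):
        raise ValueError("tracks are on different genomes or bin grids")
    if bin_size % track_a.bin_size != 0:
        raise ValueError("profile bin_size must be a multiple of the track bin size")
    factor = bin_size // track_a.bin_size
    expr_by_gene = None
    if expression is not None:
        expr_by_gene = dict(zip(expression["gene_id"], expression["log2fc"]))
    out: dict[str, pd.DataFrame] = {}
    for chrom in track_a.genome:
        va, vb = track_a.values[chrom], track_b.values[chrom]
        n = -(-len(va) // factor)
        pad = n * factor - len(va)
        ra = np.pad(va, (0, pad)).reshape(n, factor).sum(axis=1)
        rb = np.pad(vb, (0, pad)).reshape(n, factor).sum(axis=1)
        if track_a.total_fragments > 0:
            ra = ra * 1e6 / track_a.total_fragments
        if track_b.total_fragments > 0:
            rb = rb * 1e6 / track_b.total_fragments
        ratio = np.log2((ra + pseudocount) / (rb + pseudocount))
        kernel = np.ones(smooth_bins)
        smooth = np.convolve(ratio, kernel, mode="same") / np.convolve(
            np.ones_like(ratio), kernel, mode="same"
        )
        df = pd.DataFrame(
            {
                "start": np.arange(n) * bin_size,
                "end": np.minimum((np.arange(n) + 1) * bin_size, track_a.genome.length(chrom)),
                "log2_ratio": ratio,
                "smoothed_log2_ratio": smooth,
            }
        )
        if genes is not None and expr_by_gene is not None:
            sums = np.zeros(n)
            cnts = np.zeros(n)
            for g in genes:
                if g.chrom != chrom or g.gene_id not in expr_by_gene:
                    continue
                b = min(g.tss // bin_size, n - 1)
                sums[b] += expr_by_gene[g.gene_id]
                cnts[b] += 1
            with np.errstate(invalid="ignore"):
                df["expression_log2fc"] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        out[chrom] = df
    return out


def composition_stats(
    regions: Sequence[Island | StitchedRegion | Interval],
    genes: Sequence[GeneAnnotation],
    cpg_intervals: Sequence[Interval],
) -> CompositionStats:
    """CpG islands and gene TSSs per kb of region.

    A CpG island counts if its midpoint lies in a region; a gene counts if
    its TSS does.
    """
    total_bp = sum(r.end - r.start for r in regions)
    if total_bp == 0:
        raise ValueError("regions have zero total length")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for spans in by_chrom.values():
        spans.sort()

    def _contains(chrom: str, pos: int) -> bool:
        spans = by_chrom.get(chrom)
        if not spans:
            return False
        starts = [s for s, _ in spans]
        i = np.searchsorted(starts, pos, side="right") - 1
        return i >= 0 and spans[i][0] <= pos < spans[i][1]

    n_cpg = sum(_contains(c.chrom, (c.start + c.end) // 2) for c in cpg_intervals)
    n_genes = sum(_contains(g.chrom, g.tss) for g in genes)
    kb = total_bp / 1000.0
    return CompositionStats(n_cpg / kb, n_genes / kb, kb, n_cpg, n_genes)
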