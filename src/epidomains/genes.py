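"""Region-to-gene relationships.

Promoter windows (strand-aware TSS +/- 5 kb by default), island-embedded
gene signatures, nearest-TSS assignment of regulatory regions to genes,
enrichment of promoters at island boundaries, and metagene density profiles
over scaled region bodies with fixed-width flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import CoverageTrack, GeneAnnotation, Genome, Interval

__all__ = [
    "PROMOTER_FLANK",
    "BoundaryEnrichment",
    "MetageneProfile",
    "promoters",
    "genes_in_islands",
    "nearest_gene",
    "boundary_enrichment",
    "metagene_profile",
]

PROMOTER_FLANK = 5_000


@dataclass(frozen=True)
class BoundaryEnrichment:
    """Promoter enrichment at island boundary zones vs a binomial null."""

    p_value: float
    fold: float
    observed: int
    expected: float
    n_promoters: int
    boundary_width: int
    boundary_fraction: float


@dataclass(frozen=True)
class MetageneProfile:
    """Mean density per bin over scaled region bodies plus fixed flanks."""

    values: np.ndarray  # flank_bins + n_bins + flank_bins entries
    n_bins: int
    flank_bins: int
    flank_bp: int
    n_regions_used: int
    n_regions_skipped: int


def promoters(
    genes: Sequence[GeneAnnotation], genome: Genome, flank: int = PROMOTER_FLANK
) -> dict[str, Interval]:
    """One promoter window [TSS - flank, TSS + flank) per gene, clipped."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    out: dict[str, Interval] = {}
    for g in genes:
        L = genome.length(g.chrom)
        start = max(0, g.tss - flank)
        end = min(L, g.tss + flank)
        out[g.gene_id] = Interval(g.chrom, start, end, g.gene_id, 0.0, g.strand)
    return out


def genes_in_islands(
    islands: Sequence, promoter_set: dict[str, Interval], require_containment: bool = False
) -> set[str]:
    """Gene ids whose promoter window overlaps (>= 1 bp) any island.

    With ``require_containment`` the stricter reading is applied: the whole
    promoter window must lie inside a single island.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append((isl.start, isl.end))
    for spans in by_chrom.values():
        spans.sort()
    hits: set[str] = set()
    for gid, prom in promoter_set.items():
        for s, e in by_chrom.get(prom.chrom, ()):
            if s >= prom.end:
                break
            if require_containment:
                if s <= prom.start and prom.end <= e:
                    hits.add(gid)
                    break
            elif e > prom.start:
                hits.add(gid)
                break
    return hits


def nearest_gene(
    regions: Sequence, genes: Sequence[GeneAnnotation]
) -> dict[int, str | None]:
    """Assign each region (by index) the gene with the nearest TSS.

    Distance is 0 when the TSS lies inside the region; ties break to the
    lexicographically smaller gene_id; a chromosome without genes yields
    None for its regions.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for lst in by_chrom.values():
        lst.sort()
    out: dict[int, str | None] = {}
    for i, r in enumerate(regions):
        cands = by_chrom.get(r.chrom)
        if not cands:
            out[i] = None
            continue
        best: tuple[int, str] | None = None
        for tss, gid in cands:
            # gap to the half-open interval: 0 inside, else distance to the
            # nearer boundary coordinate
            d = max(0, r.start - tss, tss - r.end)
            key = (d, gid)
            if best is None or key < best:
                best = key
        out[i] = best[1]
    return out


def boundary_enrichment(
    islands: Sequence,
    promoter_set: dict[str, Interval],
    genome: Genome,
    boundary_width: int = 10_000,
) -> BoundaryEnrichment:
    """Are promoters concentrated at island boundaries?

    The boundary zone is the first and last ``boundary_width`` bp of each
    island (islands not longer than 2 x boundary_width are excluded). Each
    island-resident promoter is assigned by its center (the TSS) to either
    a boundary zone or the interior, and the boundary count is tested
    against Binomial(n, p = boundary bp / island bp) with a two-sided mid-p
    (mid-p keeps the discrete null close to uniform).
    """
    zones: dict[str, list[tuple[int, int]]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    island_bp = boundary_bp = 0
    n_qualifying = 0
    for isl in islands:
        if isl.end - isl.start <= 2 * boundary_width:
            continue
        n_qualifying += 1
        spans.setdefault(isl.chrom, []).append((isl.start, isl.end))
        zones.setdefault(isl.chrom, []).append((isl.start, isl.start + boundary_width))
        zones.setdefault(isl.chrom, []).append((isl.end - boundary_width, isl.end))
        island_bp += isl.end - isl.start
        boundary_bp += 2 * boundary_width
    if n_qualifying == 0:
        raise ValueError(
            f"no islands longer than 2 x boundary_width ({2 * boundary_width} bp)"
        )

    def _in(spanmap: dict[str, list[tuple[int, int]]], chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in spanmap.get(chrom, ()))

    n = observed = 0
    for prom in promoter_set.values():
        center = (prom.start + prom.end) // 2
        if _in(spans, prom.chrom, center):
            n += 1
            if _in(zones, prom.chrom, center):
                observed += 1
    p_boundary = boundary_bp / island_bp
    expected = n * p_boundary
    if n == 0:
        return BoundaryEnrichment(1.0, float("nan"), 0, 0.0, 0, boundary_width, p_boundary)
    # two-sided mid-p: 2 * min(mid-p lower, mid-p upper), capped at 1
    pmf = stats.binom.pmf(observed, n, p_boundary)
    upper = stats.binom.sf(observed, n, p_boundary) + 0.5 * pmf
    lower = stats.binom.cdf(observed - 1, n, p_boundary) + 0.5 * pmf
    p_value = float(min(1.0, 2 * min(upper, lower)))
    fold = observed / expected if expected > 0 else float("inf")
    return BoundaryEnrichment(
        p_value, fold, observed, expected, n, boundary_width, p_boundary
    )


def metagene_profile(
    track: CoverageTrack,
    regions: Sequence,
    n_bins: int = 50,
    flank_bp: int = 0,
    flank_bins: int = 0,
) -> MetageneProfile:
    """Average density over regions scaled to a common body + flank grid.

    Each region body is split into ``n_bins`` equal spans (oriented 5'->3'
    for stranded regions), flanks of ``flank_bp`` into ``flank_bins`` spans,
    and the per-bin mean per-base density is averaged across regions with
    equal weight per region. Regions shorter than ``n_bins`` bp are skipped
    and counted.
    """
    if not regions:
        raise ValueError("no regions for metagene profile")
    if (flank_bp > 0) != (flank_bins > 0):
        raise ValueError("flank_bp and flank_bins must be given together")
    total = np.zeros(flank_bins + n_bins + flank_bins)
    used = skipped = 0
    for r in regions:
        length = r.end - r.start
        if length < n_bins:
            skipped += 1
            continue
        vals = []
        if flank_bins:
            edges = np.linspace(r.start - flank_bp, r.start, flank_bins + 1)
            vals.extend(_mean_span(track, r.chrom, edges))
        edges = np.linspace(r.start, r.end, n_bins + 1)
        vals.extend(_mean_span(track, r.chrom, edges))
        if flank_bins:
            edges = np.linspace(r.end, r.end + flank_bp, flank_bins + 1)
            vals.extend(_mean_span(track, r.chrom, edges))
        prof = np.array(vals)
        if getattr(r, "strand", ".") == "-":
            prof = prof[::-1]
        total += prof
        used += 1
    if used == 0:
        raise ValueError("all regions shorter than n_bins; nothing to average")
    return MetageneProfile(total / used, n_bins, flank_bins, flank_bp, used, skipped)


def _mean_span(track: CoverageTrack, chrom: str, edges: np.ndarray) -> list[float]:
    L = track.genome.length(chrom)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        a, b = max(0.0, lo), min(float(L), hi)
        if b <= a:
            out.append(0.0)
            continue
        out.append(_fractional_sum(track, chrom, a, b) / (b - a))
    return out


def _fractional_sum(track: CoverageTrack, chrom: str, lo: float, hi: float) -> float:
    """Per-base signal sum over a real-valued span (bins as uniform density)."""
    v = track.values[chrom]
    bsz = track.bin_size
    first, last = int(lo // bsz), int(np.ceil(hi / bsz)) - 1
    last = min(last, len(v) - 1)
    if first > last:
        return 0.0
    if first == last:
        return float(v[first] * (hi - lo))
    total = v[first] * ((first + 1) * bsz - lo) + v[last] * (hi - last * bsz)
    if last - first > 1:
        total += v[first + 1 : last].sum() * bsz
    return float(total)
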