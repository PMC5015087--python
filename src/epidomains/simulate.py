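"""Seeded generator for a toy two-condition epigenomic study.

The scenario emulates the statistical structure of an NSD2
overexpression/knock-down experiment at desk scale: a small genome carries
a handful of megabase-scale H3K36me2 islands; in the knock-down (dox)
condition the intergenic/LAD portion of each island loses a fixed fraction
of its signal while segments marked by H3K27ac (enhancers, active TSSs) or
H3K36me3 (covered CDS) retain it, and the lost ChIP mass reappears at
enhancer regions outside the islands (the redistribution seen after
knock-down) so the two libraries have equal expected size and
fragments-per-million comparisons are unbiased. Two H3K27ac samples carry
planted super-enhancers in acquired / shared / other ratio bands. Genes are
placed with a configurable density bias away from islands (3.5x by
default), CpG islands are twice as dense outside islands as inside, and
island-embedded genes are downregulated in the knock-down expression table
(mean log2 fold change -1). All randomness flows from one seed through a
fixed generator hierarchy; the planted truth is fully recorded in a
manifest.

Counts are Poisson per planted segment with uniform placement within the
segment, matching the island caller's background model so that parameter
recovery is well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    Fragment,
    GeneAnnotation,
    Genome,
    Interval,
    write_bed,
    write_expression_table,
    write_fragments,
    write_gene_table,
    write_gmt,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "generate_scenario",
    "write_bundle",
    "truth_report",
    "interval_jaccard",
]

RETAINED_CLASSES = ("K27ac_enhancers", "K27ac_TSS", "CDS_K36me3")
LOSING_CLASSES = ("intergenic", "LADs", "CDS_wo_K36me3")
READ_LENGTH = 36


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the synthetic scenario.

    Densities are fragments per kb; ``depth_scale`` multiplies every ChIP
    density uniformly (1.0 is the standard desk-scale depth of 30
    fragments/kb inside islands).
    """

    seed: int = 7
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_islands: int = 6
    island_span: tuple[int, int] = (200_000, 1_000_000)
    island_density: float = 30.0
    background_density: float = 3.0
    intergenic_loss_fraction: float = 0.5
    depth_scale: float = 1.0
    n_superenhancers: int = 30  # split evenly acquired / shared / other
    se_length: int = 40_000
    se_background_density: float = 1.0
    se_densities: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "acquired": (50.0, 1.0),
            "shared": (25.0, 25.0),
            "other": (1.0, 25.0),
        }
    )
    n_external_enhancers: int = 30  # gain regions absorbing the lost island mass
    external_enhancer_length: int = 10_000
    # ordinary H3K36me2 regions (transcribed gene bodies outside the top
    # islands): the rank curve's tail, retained in both conditions
    n_minor_regions: int = 100
    minor_length: tuple[int, int] = (2_000, 10_000)
    minor_density: float = 20.0
    # ordinary (non-super) enhancers shared by both H3K27ac samples
    n_typical_enhancers: int = 150
    typical_enhancer_length: int = 1_500
    typical_enhancer_density: float = 25.0
    n_genes: int = 120
    gene_density_ratio: float = 3.5  # genes/kb outside vs inside islands
    n_unexpressed_genes: int = 10
    island_gene_log2fc: float = -1.0
    log2fc_sd: float = 0.3
    explicit_islands: tuple[tuple[str, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.intergenic_loss_fraction < 0 or self.intergenic_loss_fraction > 1:
            raise ValueError("intergenic_loss_fraction must be in [0, 1]")
        for v in (self.island_density, self.background_density, self.depth_scale):
            if v < 0:
                raise ValueError("densities must be >= 0")


@dataclass
class ScenarioBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: ScenarioConfig
    genome: Genome
    fragments: dict[str, list[Fragment]]
    islands: list[Interval]
    features: dict[str, list[Interval]]  # feature class -> intervals (inside islands)
    external_enhancers: list[Interval]
    minor_regions: list[Interval]
    typical_enhancers: list[Interval]
    se_regions: list[Interval]  # name field carries the planted label
    cpg_islands: list[Interval]
    genes: list[GeneAnnotation]
    island_gene_ids: list[str]
    expression: pd.DataFrame
    gene_sets: dict[str, list[str]]
    manifest: dict


# ---------------------------------------------------------------------------
# placement helpers


def _stick_break(rng: np.random.Generator, total: int, parts: int) -> np.ndarray:
    """Split ``total`` into ``parts`` non-negative integers, random, summing exactly."""
    if parts == 1:
        return np.array([total])
    cuts = np.sort(rng.integers(0, total + 1, size=parts - 1))
    return np.diff(np.concatenate(([0], cuts, [total])))


def _place_in_span(
    rng: np.random.Generator, span: tuple[int, int], lengths: Sequence[int], min_gap: int
) -> list[tuple[int, int]]:
    """Place non-overlapping intervals of the given lengths inside a span."""
    lo, hi = span
    free = (hi - lo) - sum(lengths) - min_gap * (len(lengths) + 1)
    if free < 0:
        raise ValueError(f"span {span} too small for requested intervals")
    gaps = _stick_break(rng, free, len(lengths) + 1)
    out = []
    pos = lo
    for g, ln in zip(gaps, lengths):
        pos += int(g) + min_gap
        out.append((int(pos), int(pos + ln)))
        pos += int(ln)
    return out


def _complement(genome: Genome, intervals: Sequence[Interval], margin: int = 0) -> list[Interval]:
    """Free zones: the genome minus intervals padded by ``margin``."""
    out = []
    for chrom in genome:
        L = genome.length(chrom)
        occupied = sorted(
            (max(0, iv.start - margin), min(L, iv.end + margin))
            for iv in intervals
            if iv.chrom == chrom
        )
        pos = 0
        for s, e in occupied:
            if s > pos:
                out.append(Interval(chrom, pos, s))
            pos = max(pos, e)
        if pos < L:
            out.append(Interval(chrom, pos, L))
    return out


def _scatter_points(
    rng: np.random.Generator, zones: Sequence[Interval], n: int
) -> list[tuple[str, int]]:
    """n points uniform over the union of zones (deterministic given rng)."""
    lengths = np.array([len(z) for z in zones], dtype=float)
    picks = rng.choice(len(zones), size=n, p=lengths / lengths.sum())
    return [
        (zones[i].chrom, int(rng.integers(zones[i].start, zones[i].end)))
        for i in picks
    ]


def _scatter_intervals(
    rng: np.random.Generator,
    zones: Sequence[Interval],
    n: int,
    length: int | tuple[int, int],
    min_gap: int = 0,
) -> list[Interval]:
    """n non-overlapping intervals inside the zones, >= min_gap apart."""
    max_len = length if isinstance(length, int) else length[1]
    wide = [z for z in zones if len(z) >= max_len + 2]
    out: list[Interval] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    lengths = np.array([len(z) for z in wide], dtype=float)
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 500 * n:
            raise ValueError("could not place requested intervals without overlap")
        ln = length if isinstance(length, int) else int(rng.integers(*length))
        i = rng.choice(len(wide), p=lengths / lengths.sum())
        z = wide[i]
        if z.end - ln <= z.start:
            continue
        start = int(rng.integers(z.start, z.end - ln))
        if any(
            start - min_gap < e and s < start + ln + min_gap
            for s, e in occupied.get(z.chrom, ())
        ):
            continue
        occupied.setdefault(z.chrom, []).append((start, start + ln))
        out.append(Interval(z.chrom, start, start + ln))
    return sorted(out, key=lambda v: (v.chrom, v.start))


# ---------------------------------------------------------------------------
# fragment drawing


def _draw_fragments(
    rng: np.random.Generator,
    genome: Genome,
    segments: dict[str, list[tuple[int, int, float]]],
) -> list[Fragment]:
    """Poisson counts per (start, end, density/kb) segment, uniform placement."""
    frags: list[Fragment] = []
    for chrom in genome:
        L = genome.length(chrom)
        for start, end, dens in segments[chrom]:
            if dens <= 0:
                continue
            n = rng.poisson(dens * (end - start) / 1000.0)
            if n == 0:
                continue
            pos = np.sort(rng.integers(start, end, size=n))
            fwd = rng.random(n) < 0.5
            # keep the whole read inside the chromosome
            pos = np.where(fwd, np.minimum(pos, L - READ_LENGTH), pos)
            pos = np.where(fwd, pos, np.maximum(pos, READ_LENGTH - 1))
            for p, f in zip(pos, fwd):
                frags.append(Fragment(chrom, int(p), "+" if f else "-", READ_LENGTH))
    return frags


def _segments_with_density(
    genome: Genome,
    overrides: dict[str, list[tuple[int, int, float]]],
    background: float,
) -> dict[str, list[tuple[int, int, float]]]:
    """Tile each chromosome with background density, applying overrides."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in genome:
        L = genome.length(chrom)
        segs = sorted(overrides.get(chrom, []))
        full = []
        pos = 0
        for s, e, d in segs:
            if s < pos:
                raise ValueError(f"overlapping planted segments on {chrom} at {s}")
            if s > pos:
                full.append((pos, s, background))
            full.append((s, e, d))
            pos = e
        if pos < L:
            full.append((pos, L, background))
        out[chrom] = full
    return out


# ---------------------------------------------------------------------------
# scenario generation


def generate_scenario(config: ScenarioConfig | None = None) -> ScenarioBundle:
    """Build the full synthetic study bundle, deterministic given the seed."""
    cfg = config or ScenarioConfig()
    genome = Genome(dict(cfg.chrom_sizes))
    root = np.random.SeedSequence(cfg.seed)
    keys = [
        "layout", "k36_veh", "k36_dox", "k27_a", "k27_b",
        "genes", "expression", "sets",
    ]
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, root.spawn(len(keys)))}
    rng = rngs["layout"]

    islands = _plan_islands(rng, cfg, genome)
    features, retained_by_island = _plan_island_segments(rng, cfg, islands)

    margin = 20_000
    free = _complement(genome, islands, margin)
    se_regions = _plan_superenhancers(rng, cfg, free)
    placed = list(islands) + se_regions
    free2 = _complement(genome, placed, margin)
    ext_enh = _scatter_intervals(
        rng, free2, cfg.n_external_enhancers, cfg.external_enhancer_length,
        min_gap=2_000,
    )
    free3 = _complement(genome, placed + ext_enh, margin)
    minors = _scatter_intervals(
        rng, free3, cfg.n_minor_regions, cfg.minor_length, min_gap=2_000
    )
    typicals = _scatter_intervals(
        rng, free3, cfg.n_typical_enhancers, cfg.typical_enhancer_length,
        min_gap=2_000,
    )
    cpg_islands = _plan_cpg(rng, cfg, genome, islands)

    # --- H3K36me2 fragments -------------------------------------------------
    scale = cfg.depth_scale
    d_isl = cfg.island_density * scale
    d_bg = cfg.background_density * scale
    loss = cfg.intergenic_loss_fraction

    d_minor = cfg.minor_density * scale
    veh_over: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome}
    for isl in islands:
        veh_over[isl.chrom].append((isl.start, isl.end, d_isl))
    for m in minors:
        veh_over[m.chrom].append((m.start, m.end, d_minor))
    veh_segs = _segments_with_density(genome, veh_over, d_bg)

    dox_over: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome}
    lost_mass = 0.0  # expected fragments removed from islands in dox
    for isl in islands:
        retained = sorted(retained_by_island[(isl.chrom, isl.start)])
        pos = isl.start
        for s, e in retained:
            if s > pos:
                dox_over[isl.chrom].append((pos, s, d_isl * loss))
                lost_mass += (s - pos) / 1000.0 * d_isl * (1 - loss)
            dox_over[isl.chrom].append((s, e, d_isl))
            pos = e
        if pos < isl.end:
            dox_over[isl.chrom].append((pos, isl.end, d_isl * loss))
            lost_mass += (isl.end - pos) / 1000.0 * d_isl * (1 - loss)
    # redistribute the lost mass to enhancers outside islands so both
    # libraries have equal expected size (FPM comparisons stay unbiased)
    ext_kb = sum(len(e) for e in ext_enh) / 1000.0
    gain_density = lost_mass / ext_kb if ext_kb > 0 else 0.0
    for e in ext_enh:
        dox_over[e.chrom].append((e.start, e.end, d_bg + gain_density))
    for m in minors:  # ordinary regions keep their signal in both conditions
        dox_over[m.chrom].append((m.start, m.end, d_minor))
    dox_segs = _segments_with_density(genome, dox_over, d_bg)

    fragments = {
        "k36me2_vehicle": _draw_fragments(rngs["k36_veh"], genome, veh_segs),
        "k36me2_dox": _draw_fragments(rngs["k36_dox"], genome, dox_segs),
    }

    # --- H3K27ac fragments (two samples, planted super-enhancers) ----------
    d_typ = cfg.typical_enhancer_density * scale
    for sample, key, idx in (("a", "k27_a", 0), ("b", "k27_b", 1)):
        over: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome}
        for se in se_regions:
            dens = cfg.se_densities[se.name][idx] * scale
            over[se.chrom].append((se.start, se.end, dens))
        for t in typicals:  # ordinary enhancers, shared between samples
            over[t.chrom].append((t.start, t.end, d_typ))
        segs = _segments_with_density(genome, over, cfg.se_background_density * scale)
        fragments[f"k27ac_{sample}"] = _draw_fragments(rngs[key], genome, segs)

    # --- genes and expression ----------------------------------------------
    genes, island_gene_ids = _plan_genes(rngs["genes"], cfg, genome, islands)
    expression = _plan_expression(rngs["expression"], cfg, genes, island_gene_ids)
    gene_sets = _plan_gene_sets(rngs["sets"], genes, island_gene_ids)

    manifest = {
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "islands": [[i.chrom, i.start, i.end] for i in islands],
        "island_gene_ids": sorted(island_gene_ids),
        "superenhancers": [[s.chrom, s.start, s.end, s.name] for s in se_regions],
        "external_enhancers": [[e.chrom, e.start, e.end] for e in ext_enh],
        "minor_regions": [[m.chrom, m.start, m.end] for m in minors],
        "typical_enhancers": [[t.chrom, t.start, t.end] for t in typicals],
        "planted_log2fc": {
            **{c: float(np.log2(loss)) if loss > 0 else float("-inf") for c in LOSING_CLASSES},
            **{c: 0.0 for c in RETAINED_CLASSES},
        },
        "gain_density_per_kb": float(gain_density),
        "expected_fragments": {
            "k36me2_vehicle": float(
                sum((e - s) / 1000.0 * d for segs in veh_segs.values() for s, e, d in segs)
            ),
            "k36me2_dox": float(
                sum((e - s) / 1000.0 * d for segs in dox_segs.values() for s, e, d in segs)
            ),
        },
    }
    return ScenarioBundle(
        cfg, genome, fragments, islands, features, ext_enh, minors, typicals,
        se_regions, cpg_islands, genes, sorted(island_gene_ids), expression,
        gene_sets, manifest,
    )


def _config_dict(cfg: ScenarioConfig) -> dict:
    d = asdict(cfg)
    d["explicit_islands"] = (
        [list(x) for x in cfg.explicit_islands] if cfg.explicit_islands else None
    )
    return d


def _plan_islands(
    rng: np.random.Generator, cfg: ScenarioConfig, genome: Genome
) -> list[Interval]:
    if cfg.explicit_islands is not None:
        islands = [Interval(c, s, e, "island") for c, s, e in cfg.explicit_islands]
        by_chrom: dict[str, list[Interval]] = {}
        for isl in islands:
            by_chrom.setdefault(isl.chrom, []).append(isl)
        for chrom, lst in by_chrom.items():
            lst.sort(key=lambda i: i.start)
            for a, b in zip(lst, lst[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"planted islands overlap on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )
        return sorted(islands, key=lambda i: (i.chrom, i.start))
    chroms = list(genome)
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(cfg.n_islands):
        per_chrom[chroms[i % len(chroms)]] += 1
    out = []
    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        lengths = [int(rng.integers(*cfg.island_span)) for _ in range(k)]
        L = genome.length(chrom)
        spans = _place_in_span(rng, (150_000, L - 150_000), lengths, min_gap=300_000)
        out.extend(Interval(chrom, s, e, "island") for s, e in spans)
    return sorted(out, key=lambda i: (i.chrom, i.start))


_SEGMENT_PLAN = [
    ("K27ac_enhancers", 10_000),
    ("CDS_K36me3", 10_000),
    ("K27ac_TSS", 4_000),
    ("CDS_wo_K36me3", 10_000),
    ("LADs", 40_000),
    ("intergenic", 20_000),
]


def _plan_island_segments(
    rng: np.random.Generator, cfg: ScenarioConfig, islands: Sequence[Interval]
) -> tuple[dict[str, list[Interval]], dict[tuple[str, int], list[tuple[int, int]]]]:
    """Lay out feature segments inside each island.

    Large islands (> 500 kb) get two copies of each segment class. The
    returned ``retained`` map drives the dox density model: K27ac/K36me3
    segments keep the vehicle density, everything else in the island loses.
    """
    features: dict[str, list[Interval]] = {name: [] for name, _ in _SEGMENT_PLAN}
    retained: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for isl in islands:
        copies = 2 if len(isl) > 500_000 else 1
        plan = [(name, ln) for name, ln in _SEGMENT_PLAN for _ in range(copies)]
        inner = (isl.start + 20_000, isl.end - 20_000)
        spans = _place_in_span(rng, inner, [ln for _, ln in plan], min_gap=5_000)
        keep = []
        for (name, _), (s, e) in zip(plan, spans):
            features[name].append(Interval(isl.chrom, s, e, name))
            if name in RETAINED_CLASSES:
                keep.append((s, e))
        retained[(isl.chrom, isl.start)] = keep
    return features, retained


def _plan_superenhancers(
    rng: np.random.Generator, cfg: ScenarioConfig, free: Sequence[Interval]
) -> list[Interval]:
    n = cfg.n_superenhancers
    labels = ["acquired", "shared", "other"]
    counts = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    regions = _scatter_intervals(rng, free, n, cfg.se_length)
    out = []
    i = 0
    for label, k in zip(labels, counts):
        for _ in range(k):
            r = regions[i]
            out.append(Interval(r.chrom, r.start, r.end, label))
            i += 1
    return out


def _plan_cpg(
    rng: np.random.Generator, cfg: ScenarioConfig, genome: Genome, islands: Sequence[Interval]
) -> list[Interval]:
    """CpG islands (1 kb), twice as dense outside islands as inside."""
    inside_kb = sum(len(i) for i in islands) / 1000.0
    outside_kb = genome.total_length / 1000.0 - inside_kb
    d_out, d_in = 0.01, 0.005  # per kb
    pts: list[tuple[str, int]] = []
    n_in = rng.poisson(d_in * inside_kb)
    n_out = rng.poisson(d_out * outside_kb)
    pts += _scatter_points(rng, list(islands), n_in)
    pts += _scatter_points(rng, _complement(genome, islands), n_out)
    out = []
    for chrom, p in sorted(pts):
        end = min(genome.length(chrom), p + 1000)
        if end > p:
            out.append(Interval(chrom, p, end, "cpg"))
    return out


def _plan_genes(
    rng: np.random.Generator, cfg: ScenarioConfig, genome: Genome, islands: Sequence[Interval]
) -> tuple[list[GeneAnnotation], list[str]]:
    """Place genes with density biased away from islands by gene_density_ratio."""
    inside_kb = sum(len(i) for i in islands) / 1000.0
    outside_kb = genome.total_length / 1000.0 - inside_kb
    # d_out = ratio * d_in; n = d_in*inside + d_out*outside
    d_in = cfg.n_genes / (inside_kb + cfg.gene_density_ratio * outside_kb)
    n_in = int(round(d_in * inside_kb))
    n_out = cfg.n_genes - n_in
    inner_islands = [
        Interval(i.chrom, i.start + 25_000, i.end - 25_000) for i in islands
    ]
    far_outside = _complement(genome, islands, margin=20_000)
    genes: list[GeneAnnotation] = []
    island_ids: list[str] = []

    def _make(gid: str, chrom: str, tss: int) -> GeneAnnotation:
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(2_000, 20_000))
        L = genome.length(chrom)
        if strand == "+":
            start, end = tss, min(L, tss + length)
            if end - start < 200:
                start, end = max(0, tss - length), tss + 200
        else:
            start, end = max(0, tss - length), tss
            if end - start < 200:
                start, end = start, min(L, tss + 200)
        pad = (end - start) // 10
        return GeneAnnotation(gid, chrom, strand, start, end, start + pad, end - pad)

    for j, (chrom, tss) in enumerate(_scatter_points(rng, inner_islands, n_in)):
        g = _make(f"ISL{j:04d}", chrom, tss)
        genes.append(g)
        island_ids.append(g.gene_id)
    pts = _scatter_points(rng, far_outside, n_out + cfg.n_unexpressed_genes)
    for j, (chrom, tss) in enumerate(pts[:n_out]):
        genes.append(_make(f"BG{j:04d}", chrom, tss))
    for j, (chrom, tss) in enumerate(pts[n_out:]):
        genes.append(_make(f"OFF{j:04d}", chrom, tss))
    return genes, island_ids


def _plan_expression(
    rng: np.random.Generator,
    cfg: ScenarioConfig,
    genes: Sequence[GeneAnnotation],
    island_gene_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-gene expression: island genes downregulated in dox (condition a)."""
    island = set(island_gene_ids)
    rows = []
    for g in genes:
        off = g.gene_id.startswith("OFF")
        if off:
            fpkm_b = float(rng.uniform(0.001, 0.04))
            lfc = 0.0
        else:
            fpkm_b = float(rng.lognormal(1.0, 1.0)) + 0.1
            mu = cfg.island_gene_log2fc if g.gene_id in island else 0.0
            lfc = float(rng.normal(mu, cfg.log2fc_sd))
        fpkm_a = fpkm_b * 2.0**lfc
        stat = lfc / cfg.log2fc_sd
        rows.append((g.gene_id, fpkm_a, fpkm_b, lfc, stat))
    df = pd.DataFrame(rows, columns=["gene_id", "fpkm_a", "fpkm_b", "log2fc", "stat"])
    p = 2 * stats.norm.sf(np.abs(df["stat"]))
    df["fdr"] = stats.false_discovery_control(p, method="bh")
    return df


def _plan_gene_sets(
    rng: np.random.Generator, genes: Sequence[GeneAnnotation], island_gene_ids: Sequence[str]
) -> dict[str, list[str]]:
    planted = sorted(island_gene_ids)
    background = sorted(g.gene_id for g in genes if g.gene_id not in set(planted))
    sets = {"ISLAND_SIGNATURE": planted}
    for i in (1, 2):
        k = min(15, len(background))
        pick = rng.choice(len(background), size=k, replace=False)
        sets[f"RANDOM_SET_{i}"] = sorted(background[j] for j in pick)
    return sets


# ---------------------------------------------------------------------------
# output + truth report


def write_bundle(bundle: ScenarioBundle, outdir: str | Path) -> None:
    """Write every generated input as plain-text files plus the truth manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.sizes", "w") as fh:
        for chrom in bundle.genome:
            fh.write(f"{chrom}\t{bundle.genome.length(chrom)}\n")
    for name, frags in bundle.fragments.items():
        with open(out / f"{name}.bed", "w") as fh:
            write_fragments(frags, fh)
    with open(out / "islands_truth.bed", "w") as fh:
        write_bed(bundle.islands, fh)
    for cls, feats in bundle.features.items():
        with open(out / f"features_{cls}.bed", "w") as fh:
            write_bed(feats, fh)
    with open(out / "superenhancers_truth.bed", "w") as fh:
        write_bed(bundle.se_regions, fh)
    with open(out / "minor_regions.bed", "w") as fh:
        write_bed(bundle.minor_regions, fh)
    with open(out / "typical_enhancers.bed", "w") as fh:
        write_bed(bundle.typical_enhancers, fh)
    with open(out / "external_enhancers.bed", "w") as fh:
        write_bed(bundle.external_enhancers, fh)
    with open(out / "cpg_islands.bed", "w") as fh:
        write_bed(bundle.cpg_islands, fh)
    with open(out / "genes.tsv", "w") as fh:
        write_gene_table(bundle.genes, fh)
    with open(out / "expression.tsv", "w") as fh:
        write_expression_table(bundle.expression, fh)
    with open(out / "gene_sets.gmt", "w") as fh:
        write_gmt(bundle.gene_sets, fh)
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _interval_union_bp(intervals: Sequence) -> dict[str, np.ndarray]:
    spans: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, lst in spans.items():
        lst.sort()
        merged = []
        for s, e in lst:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[chrom] = np.array(merged)
    return out


def interval_jaccard(set_a: Sequence, set_b: Sequence) -> float:
    """Base-pair Jaccard index between two interval sets."""
    ua, ub = _interval_union_bp(set_a), _interval_union_bp(set_b)
    inter = union = 0
    for chrom in set(ua) | set(ub):
        a = ua.get(chrom, np.empty((0, 2), dtype=int))
        b = ub.get(chrom, np.empty((0, 2), dtype=int))
        bp_a = int((a[:, 1] - a[:, 0]).sum()) if len(a) else 0
        bp_b = int((b[:, 1] - b[:, 0]).sum()) if len(b) else 0
        ov = 0
        for s, e in a:
            for s2, e2 in b:
                ov += max(0, min(e, e2) - max(s, s2))
        inter += ov
        union += bp_a + bp_b - ov
    return inter / union if union else 0.0


def truth_report(
    bundle: ScenarioBundle,
    called_islands: Sequence | None = None,
    se_classifications: Sequence | None = None,
    signature: Sequence[str] | None = None,
    feature_changes: dict | None = None,
) -> dict:
    """Recovery metrics of pipeline outputs against the planted truth."""
    report: dict = {}
    if called_islands is not None:
        report["island_jaccard"] = interval_jaccard(called_islands, bundle.islands)
    if se_classifications is not None:
        confusion: dict[str, dict[str, int]] = {}
        correct = total = 0
        for se in bundle.se_regions:
            hit = None
            for cls in se_classifications:
                r = cls.region
                if r.chrom == se.chrom and r.start < se.end and se.start < r.end:
                    hit = cls.label
                    break
            label = hit if hit is not None else "missed"
            confusion.setdefault(se.name, {}).setdefault(label, 0)
            confusion[se.name][label] += 1
            total += 1
            correct += label == se.name
        report["se_confusion"] = confusion
        report["se_label_accuracy"] = correct / total if total else float("nan")
    if signature is not None:
        truth = set(bundle.island_gene_ids)
        called = set(signature)
        tp = len(truth & called)
        report["signature_precision"] = tp / len(called) if called else 0.0
        report["signature_recall"] = tp / len(truth) if truth else 0.0
    if feature_changes is not None:
        planted = bundle.manifest["planted_log2fc"]
        errs = {}
        for cls, change in feature_changes.items():
            if cls in planted and change.n_features:
                med = float(np.median(change.log2fc))
                errs[cls] = {
                    "median_log2fc": med,
                    "planted": planted[cls],
                    "error": med - planted[cls],
                }
        report["feature_log2fc"] = errs
    return report
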