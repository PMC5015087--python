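"""Promoters, signatures, nearest-TSS assignment, boundary test, metagenes."""

import numpy as np
import pytest
from scipy import stats as sps

from epidomains import (
    CoverageTrack,
    GeneAnnotation,
    Genome,
    Interval,
    boundary_enrichment,
    genes_in_islands,
    metagene_profile,
    nearest_gene,
    promoters,
)


def _gene(gid, chrom, strand, tss, length=10_000):
    if strand == "+":
        return GeneAnnotation(gid, chrom, strand, tss, tss + length)
    return GeneAnnotation(gid, chrom, strand, tss - length, tss)


class TestPromoters:
    def test_plus_strand_window(self):
        g = Genome({"c": 1_000_000})
        proms = promoters([_gene("a", "c", "+", 100_000)], g, flank=5_000)
        assert (proms["a"].start, proms["a"].end) == (95_000, 105_000)

    def test_clipping_at_chromosome_start(self):
        g = Genome({"c": 1_000_000})
        proms = promoters([_gene("a", "c", "+", 2_000, length=500)], g, flank=5_000)
        assert (proms["a"].start, proms["a"].end) == (0, 7_000)

    def test_minus_strand_centered_on_tx_end(self):
        g = Genome({"c": 1_000_000})
        proms = promoters([_gene("a", "c", "-", 50_000)], g, flank=5_000)
        assert (proms["a"].start, proms["a"].end) == (45_000, 55_000)


class TestGenesInIslands:
    ISLANDS = [Interval("c", 100_000, 200_000)]

    def _prom(self, start, end):
        return {"g": Interval("c", start, end)}

    def test_contained_promoter_included(self):
        assert genes_in_islands(self.ISLANDS, self._prom(150_000, 160_000)) == {"g"}

    def test_disjoint_promoter_excluded(self):
        assert genes_in_islands(self.ISLANDS, self._prom(300_000, 310_000)) == set()

    def test_single_bp_overlap_included(self):
        assert genes_in_islands(self.ISLANDS, self._prom(199_999, 210_000)) == {"g"}
        assert genes_in_islands(self.ISLANDS, self._prom(200_000, 210_000)) == set()

    def test_containment_flag_stricter(self):
        proms = self._prom(95_000, 105_000)  # straddles the edge
        assert genes_in_islands(self.ISLANDS, proms) == {"g"}
        assert genes_in_islands(self.ISLANDS, proms, require_containment=True) == set()

    def test_matches_bruteforce_intersection(self, rng):
        islands = []
        pos = 0
        for _ in range(100):
            pos += int(rng.integers(1_000, 20_000))
            islands.append(Interval("c", pos, pos + int(rng.integers(500, 15_000))))
            pos = islands[-1].end
        proms = {
            f"g{i}": Interval("c", s, s + 10_000)
            for i, s in enumerate(rng.integers(0, pos, size=300))
        }
        got = genes_in_islands(islands, proms)
        want = {
            gid
            for gid, p in proms.items()
            if any(p.start < i.end and i.start < p.end for i in islands)
        }
        assert got == want


class TestNearestGene:
    def test_tss_inside_region_wins(self):
        genes = [_gene("a", "c", "+", 1_500), _gene("b", "c", "+", 5_000)]
        out = nearest_gene([Interval("c", 1_000, 2_000)], genes)
        assert out[0] == "a"

    def test_distance_comparison(self):
        genes = [_gene("a", "c", "+", 500, 400), _gene("b", "c", "+", 2_600)]
        out = nearest_gene([Interval("c", 1_000, 2_000)], genes)
        assert out[0] == "a"  # 500 < 600

    def test_empty_chromosome_unassigned(self):
        out = nearest_gene([Interval("c2", 0, 100)], [_gene("a", "c1", "+", 10, 5)])
        assert out[0] is None

    def test_tie_breaks_lexicographically(self):
        genes = [_gene("zzz", "c", "+", 900, 200), _gene("aaa", "c", "+", 2_100)]
        out = nearest_gene([Interval("c", 1_000, 2_000)], genes)
        assert out[0] == "aaa"

    def test_translation_and_reflection_symmetry(self, rng):
        L = 100_000
        tss = sorted(int(t) for t in rng.integers(1_000, L - 1_000, 8))
        genes = [_gene(f"g{i}", "c", "+", t, 500) for i, t in enumerate(tss)]
        regions = [Interval("c", int(s), int(s) + 700) for s in rng.integers(0, L - 700, 20)]
        base = nearest_gene(regions, genes)
        shift = 5_000
        genes_t = [_gene(f"g{i}", "c", "+", t + shift, 500) for i, t in enumerate(tss)]
        regions_t = [Interval("c", r.start + shift, r.end + shift) for r in regions]
        assert nearest_gene(regions_t, genes_t) == base
        genes_r = [_gene(f"g{i}", "c", "-", L - t, 500) for i, t in enumerate(tss)]
        regions_r = [Interval("c", L - r.end, L - r.start) for r in regions]
        reflected = nearest_gene(regions_r, genes_r)
        # distances are preserved; ties may resolve differently, so compare distance
        by_tss = {f"g{i}": t for i, t in enumerate(tss)}

        def dist(region, t):
            return max(0, region.start - t, t - region.end)

        for i, r in enumerate(regions_r):
            d_ref = dist(r, L - by_tss[reflected[i]])
            d_base = dist(regions[i], by_tss[base[i]])
            assert d_ref == d_base


class TestBoundaryEnrichment:
    def _islands(self):
        return [Interval("c", i * 200_000, i * 200_000 + 100_000) for i in range(10)]

    def test_all_promoters_at_boundaries_extreme(self):
        g = Genome({"c": 2_000_000})
        proms = {
            f"g{i}": Interval("c", isl.start + 2_000, isl.start + 12_000)
            for i, isl in enumerate(self._islands())
        }
        res = boundary_enrichment(self._islands(), proms, g, boundary_width=10_000)
        assert res.fold == pytest.approx(100_000 / 20_000)
        assert res.p_value < 1e-6

    def test_degenerate_boundary_covers_island(self):
        g = Genome({"c": 2_000_000})
        islands = [Interval("c", 0, 100_000)]
        proms = {"g": Interval("c", 45_000, 55_000)}
        with pytest.raises(ValueError):
            # boundary_width * 2 == island length -> no qualifying islands
            boundary_enrichment(islands, proms, g, boundary_width=50_000)

    def test_uniform_promoters_not_significant(self, rng):
        g = Genome({"c": 2_000_000})
        islands = self._islands()
        proms = {}
        k = 0
        for isl in islands:
            for t in rng.integers(isl.start, isl.end, 40):
                proms[f"g{k}"] = Interval("c", max(0, int(t) - 5_000), int(t) + 5_000)
                k += 1
        res = boundary_enrichment(islands, proms, g, boundary_width=10_000)
        assert 0.5 < res.fold < 1.6
        assert res.p_value > 0.001


class TestMetagene:
    def _track(self, values, bin_size=1):
        g = Genome({"c": len(values) * bin_size})
        return CoverageTrack(g, bin_size, {"c": np.asarray(values, float)}, normalized=True)

    def test_uniform_density_flat_profile(self):
        t = self._track(np.ones(10_000))
        prof = metagene_profile(t, [Interval("c", 1_000, 3_000)], n_bins=10,
                                flank_bp=500, flank_bins=5)
        np.testing.assert_allclose(prof.values, 1.0, atol=1e-12)

    def test_region_enriched_over_flanks(self):
        v = np.zeros(10_000)
        v[2_000:4_000] = 2.0
        t = self._track(v)
        prof = metagene_profile(t, [Interval("c", 2_000, 4_000)], n_bins=8,
                                flank_bp=1_000, flank_bins=4)
        assert np.allclose(prof.values[4:12], 2.0)
        assert (prof.values[:4] < 2.0).all() and (prof.values[12:] < 2.0).all()

    def test_triangular_density_matches_per_base_oracle(self):
        v = np.abs(np.arange(1_000) - 500.0)
        t = self._track(v)
        region = Interval("c", 100, 900)
        prof = metagene_profile(t, [region], n_bins=4)
        expected = [v[100 + 200 * i : 100 + 200 * (i + 1)].mean() for i in range(4)]
        np.testing.assert_allclose(prof.values, expected, rtol=1e-12)

    def test_minus_strand_profile_mirrored(self):
        v = np.linspace(0, 1, 1_000)
        t = self._track(v)
        plus = metagene_profile(t, [Interval("c", 100, 900, strand="+")], n_bins=8)
        minus = metagene_profile(t, [Interval("c", 100, 900, strand="-")], n_bins=8)
        np.testing.assert_allclose(minus.values, plus.values[::-1], rtol=1e-12)

    def test_short_regions_skipped_and_counted(self):
        t = self._track(np.ones(1_000))
        prof = metagene_profile(
            t, [Interval("c", 0, 5), Interval("c", 100, 400)], n_bins=50
        )
        assert prof.n_regions_used == 1 and prof.n_regions_skipped == 1

    def test_all_short_raises(self):
        t = self._track(np.ones(100))
        with pytest.raises(ValueError):
            metagene_profile(t, [Interval("c", 0, 10)], n_bins=50)
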