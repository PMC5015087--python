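"""Two-condition comparisons: subtraction, SE classes, fold changes, profiles."""

import numpy as np
import pytest

from epidomains import (
    CoverageTrack,
    Fragment,
    Genome,
    Interval,
    classify_superenhancers,
    composition_stats,
    coverage_from_fragments,
    feature_log2fc,
    losing_islands,
    smoothed_ratio_profile,
    subtraction_track,
)
from epidomains.differential import merge_intervals
from epidomains.genome import GeneAnnotation

from oracles import oracle_paired_t


def _raw_track(genome, values, total, bin_size=1):
    return CoverageTrack(genome, bin_size, dict(values), total_fragments=total)


class TestSubtraction:
    def test_self_subtraction_is_zero(self):
        g = Genome({"c": 100})
        t = _raw_track(g, {"c": np.arange(100, dtype=float)}, total=50)
        sub = subtraction_track(t, t)
        assert (sub.values["c"] == 0).all()

    def test_read_fraction_arithmetic(self):
        g = Genome({"c": 10})
        a = _raw_track(g, {"c": np.array([2.0] + [0.0] * 9)}, total=10)
        b = _raw_track(g, {"c": np.array([2.0] + [0.0] * 9)}, total=20)
        sub = subtraction_track(a, b)
        assert sub.values["c"][0] == pytest.approx(0.1)

    def test_antisymmetric(self, rng):
        g = Genome({"c": 200})
        a = _raw_track(g, {"c": rng.poisson(3, 200).astype(float)}, total=600)
        b = _raw_track(g, {"c": rng.poisson(2, 200).astype(float)}, total=400)
        ab, ba = subtraction_track(a, b), subtraction_track(b, a)
        np.testing.assert_allclose(ab.values["c"], -ba.values["c"], atol=1e-15)

    def test_in_bounds_fragments_sum_to_zero(self, rng):
        g = Genome({"c": 5_000})
        fa = [Fragment("c", int(rng.integers(300, 4_700)), "+", 36) for _ in range(400)]
        fb = [Fragment("c", int(rng.integers(300, 4_700)), "-", 36) for _ in range(250)]
        ta = coverage_from_fragments(fa, g, 1, 260)
        tb = coverage_from_fragments(fb, g, 1, 260)
        sub = subtraction_track(ta, tb)
        # every fragment contributes exactly 260 covered bases in each library
        assert sub.values["c"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_grid_mismatch_raises(self):
        g = Genome({"c": 100})
        a = _raw_track(g, {"c": np.zeros(100)}, 10, bin_size=1)
        b = _raw_track(g, {"c": np.zeros(50)}, 10, bin_size=2)
        with pytest.raises(ValueError):
            subtraction_track(a, b)


class TestSEClassification:
    def _tracks(self, genome, dens_a, dens_b):
        # normalized tracks holding per-bp FPM densities directly
        a = CoverageTrack(genome, 1, {"c": dens_a.astype(float)}, normalized=True)
        b = CoverageTrack(genome, 1, {"c": dens_b.astype(float)}, normalized=True)
        return a, b

    @pytest.mark.parametrize(
        "da,db,label", [(30.0, 2.0, "acquired"), (3.0, 2.0, "shared"), (1.0, 10.0, "other")]
    )
    def test_printed_ratio_bands(self, da, db, label):
        g = Genome({"c": 1_000})
        a, b = self._tracks(g, np.full(1_000, da), np.full(1_000, db))
        (cls,) = classify_superenhancers([Interval("c", 0, 1_000)], [], a, b)
        assert cls.label == label

    def test_union_merging_bookended(self):
        g = Genome({"c": 1_000})
        a, b = self._tracks(g, np.ones(1_000), np.ones(1_000))
        out = classify_superenhancers(
            [Interval("c", 0, 100)], [Interval("c", 100, 300), Interval("c", 500, 600)], a, b
        )
        assert [(c.region.start, c.region.end) for c in out] == [(0, 300), (500, 600)]

    def test_labels_partition(self, rng):
        g = Genome({"c": 10_000})
        a, b = self._tracks(g, rng.gamma(1, 5, 10_000), rng.gamma(1, 5, 10_000))
        regions = [Interval("c", i * 500, i * 500 + 400) for i in range(20)]
        out = classify_superenhancers(regions, [], a, b)
        assert len(out) == 20
        assert all(c.label in {"acquired", "shared", "other"} for c in out)


class TestMergeIntervals:
    def test_overlap_and_bookend(self):
        merged = merge_intervals(
            [Interval("c", 0, 10), Interval("c", 5, 20), Interval("c", 20, 30), Interval("c", 40, 50)]
        )
        assert [(m.start, m.end) for m in merged] == [(0, 30), (40, 50)]


class TestFeatureLog2fc:
    def test_halved_density_gives_minus_one(self):
        g = Genome({"c": 1_000})
        dox = CoverageTrack(g, 1, {"c": np.full(1_000, 5.0)}, normalized=True)
        veh = CoverageTrack(g, 1, {"c": np.full(1_000, 10.0)}, normalized=True)
        out = feature_log2fc(dox, veh, {"x": [Interval("c", 0, 500), Interval("c", 500, 1_000)]})
        assert out["x"].log2fc == pytest.approx([-1.0, -1.0], abs=5e-3)  # pseudocount

    def test_identical_tracks_flagged(self):
        g = Genome({"c": 100})
        t = CoverageTrack(g, 1, {"c": np.ones(100)}, normalized=True)
        out = feature_log2fc(t, t, {"x": [Interval("c", 0, 50), Interval("c", 50, 100)]})
        assert np.allclose(out["x"].log2fc, 0.0)
        assert np.isnan(out["x"].paired_t_p)  # constant difference

    def test_single_feature_p_undefined(self):
        g = Genome({"c": 100})
        t = CoverageTrack(g, 1, {"c": np.ones(100)}, normalized=True)
        t2 = CoverageTrack(g, 1, {"c": np.full(100, 2.0)}, normalized=True)
        out = feature_log2fc(t2, t, {"x": [Interval("c", 0, 100)]})
        assert np.isnan(out["x"].paired_t_p)

    def test_paired_t_matches_textbook(self, rng):
        g = Genome({"c": 10_000})
        dox = CoverageTrack(g, 1, {"c": rng.gamma(2, 2, 10_000)}, normalized=True)
        veh = CoverageTrack(g, 1, {"c": rng.gamma(2, 2, 10_000)}, normalized=True)
        feats = [Interval("c", i * 500, i * 500 + 400) for i in range(20)]
        out = feature_log2fc(dox, veh, {"x": feats})
        da = [dox.region_density(f.chrom, f.start, f.end) for f in feats]
        dv = [veh.region_density(f.chrom, f.start, f.end) for f in feats]
        assert out["x"].paired_t_p == pytest.approx(oracle_paired_t(da, dv), abs=1e-10)


class TestLosingIslands:
    def _pair(self, ratio):
        g = Genome({"c": 1_000})
        veh = CoverageTrack(g, 1, {"c": np.full(1_000, 8.0)}, normalized=True)
        dox = CoverageTrack(g, 1, {"c": np.full(1_000, 8.0 * ratio)}, normalized=True)
        return dox, veh

    def test_unchanged_island_excluded(self):
        dox, veh = self._pair(1.0)
        assert losing_islands([Interval("c", 0, 1_000)], dox, veh) == []

    def test_quartered_island_included(self):
        dox, veh = self._pair(0.25)
        assert len(losing_islands([Interval("c", 0, 1_000)], dox, veh)) == 1

    def test_zero_threshold_boundary(self):
        dox, veh = self._pair(0.95)
        assert len(losing_islands([Interval("c", 0, 1_000)], dox, veh, loss_threshold=0.0)) == 1


class TestSmoothedProfile:
    def test_identical_tracks_zero_profile(self):
        g = Genome({"c": 1_000_000})
        t = CoverageTrack(g, 100, {"c": np.ones(10_000)}, total_fragments=1_000)
        prof = smoothed_ratio_profile(t, t, bin_size=100_000, smooth_bins=3)
        np.testing.assert_allclose(prof["c"]["smoothed_log2_ratio"], 0.0, atol=1e-12)

    def test_running_mean_of_constant_is_constant(self):
        g = Genome({"c": 2_000_000})
        a = CoverageTrack(g, 100, {"c": np.full(20_000, 2.0)}, total_fragments=100)
        b = CoverageTrack(g, 100, {"c": np.full(20_000, 1.0)}, total_fragments=100)
        prof = smoothed_ratio_profile(a, b, bin_size=100_000, smooth_bins=5)
        vals = prof["c"]["smoothed_log2_ratio"].to_numpy()
        np.testing.assert_allclose(vals, vals[0], atol=1e-9)

    def test_step_crossed_near_boundary(self):
        g = Genome({"c": 4_000_000})
        vb = np.ones(40_000)
        va = np.ones(40_000)
        va[20_000:] = 4.0  # step at 2 Mb
        a = CoverageTrack(g, 100, {"c": va}, total_fragments=1_000)
        b = CoverageTrack(g, 100, {"c": vb}, total_fragments=1_000)
        smooth_bins = 5
        prof = smoothed_ratio_profile(a, b, bin_size=100_000, smooth_bins=smooth_bins)
        vals = prof["c"]["smoothed_log2_ratio"].to_numpy()
        lo, hi = vals[:10].mean(), vals[-10:].mean()
        crossing = int(np.argmax(vals >= (lo + hi) / 2))
        assert abs(crossing - 20) <= smooth_bins // 2 + 1

    def test_even_smooth_bins_rejected(self):
        g = Genome({"c": 1_000})
        t = CoverageTrack(g, 100, {"c": np.ones(10)}, total_fragments=1)
        with pytest.raises(ValueError):
            smoothed_ratio_profile(t, t, 1_000, smooth_bins=4)


class TestComposition:
    def _genes(self, positions):
        return [
            GeneAnnotation(f"g{i}", "c", "+", p, p + 1_000) for i, p in enumerate(positions)
        ]

    def test_genes_per_kb(self):
        regions = [Interval("c", 0, 100_000)]
        stats = composition_stats(regions, self._genes(range(0, 100_000, 10_000)), [])
        assert stats.genes_per_kb == pytest.approx(10 / 100.0)
        assert stats.cpg_per_kb == 0.0

    def test_zero_length_raises(self):
        with pytest.raises(ValueError):
            composition_stats([], self._genes([0]), [])

    def test_gene_poor_islands(self, default_bundle):
        """Planted islands avoid gene-dense segments: density ratio near 3.5."""
        from epidomains import composition_stats as cs
        from epidomains.pipeline import _complement_intervals

        b = default_bundle
        inside = cs(b.islands, b.genes, b.cpg_islands)
        outside = cs(
            _complement_intervals(b.genome, b.islands), b.genes, b.cpg_islands
        )
        assert inside.genes_per_kb < outside.genes_per_kb
        ratio = outside.genes_per_kb / inside.genes_per_kb
        assert 2.0 < ratio < 6.0
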