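"""Window/gap island caller against direct arithmetic and a scan oracle."""

import numpy as np
import pytest
from scipy import stats

from epidomains import Fragment, Genome, IslandCallParams, call_islands
from epidomains.islands import (
    aggregate_islands,
    background_rate,
    eligible_windows,
    score_and_filter,
    window_counts,
)

from oracles import oracle_call_islands


SMALL = IslandCallParams(
    window_size=200, gap_size=600, fragment_size=260,
    fdr_threshold=0.01, window_p=0.2, effective_genome_fraction=1.0,
)


class TestWindowCounts:
    def test_plus_fragment_midpoint_window(self):
        g = Genome({"chr1": 2_000})
        counts = window_counts([Fragment("chr1", 100, "+", 36)], g, SMALL)
        # 5' = 100, midpoint 100 + 130 = 230 -> window [200, 400)
        assert counts["chr1"][1] == 1 and counts["chr1"].sum() == 1

    def test_minus_fragment_midpoint_window(self):
        g = Genome({"chr1": 2_000})
        counts = window_counts([Fragment("chr1", 359, "-", 36)], g, SMALL)
        # 5' = 359, midpoint 359 - 130 = 229 -> window [200, 400)
        assert counts["chr1"][1] == 1

    def test_empty_gives_zero_vector(self):
        g = Genome({"chr1": 1_001})
        counts = window_counts([], g, SMALL)
        assert counts["chr1"].shape == (6,) and counts["chr1"].sum() == 0

    def test_counts_conserve_fragments(self, rng):
        g = Genome({"chr1": 5_000})
        frags = [
            Fragment("chr1", int(rng.integers(0, 5_000)), str(rng.choice(["+", "-"])), 36)
            for _ in range(137)
        ]
        assert window_counts(frags, g, SMALL)["chr1"].sum() == 137


class TestBackgroundRate:
    def test_closed_form(self):
        g = Genome({"chr1": 1_000_000})
        assert background_rate(1000, g, SMALL) == pytest.approx(0.2)

    def test_effective_fraction_halves_length(self):
        g = Genome({"chr1": 1_000_000})
        params = IslandCallParams(effective_genome_fraction=0.5, window_p=0.2)
        assert background_rate(1000, g, params) == pytest.approx(0.4)

    def test_zero_fragments_error(self):
        with pytest.raises(ValueError):
            background_rate(0, Genome({"chr1": 100}), SMALL)


class TestEligibility:
    def test_zero_count_never_eligible(self):
        assert not eligible_windows(np.array([0]), 0.2, 0.99).any()

    def test_poisson_tail_threshold(self):
        # P(X >= 1 | 0.2) = 1 - e^-0.2 ~ 0.181 <= 0.2
        assert eligible_windows(np.array([1]), 0.2, 0.2)[0]
        assert not eligible_windows(np.array([1]), 0.2, 0.15)[0]

    def test_huge_count_eligible(self):
        assert eligible_windows(np.array([500]), 0.2, 1e-6)[0]


class TestAggregation:
    def _islands(self, eligible, n):
        mask = np.zeros(n, dtype=bool)
        mask[list(eligible)] = True
        return [(i.start // 200, i.end // 200) for i in aggregate_islands(mask, SMALL, "c")]

    def test_adjacent_windows_merge(self):
        assert self._islands({0, 1}, 10) == [(0, 2)]

    def test_gap_of_three_windows_allowed(self):
        assert self._islands({0, 4}, 10) == [(0, 5)]

    def test_gap_of_four_windows_splits(self):
        assert self._islands({0, 5}, 10) == [(0, 1), (5, 6)]


class TestScoring:
    def test_single_window_score_is_neg_log_pmf(self):
        # -ln pmf(5; 1) = 1 + ln 120
        g = Genome({"c": 200})
        isl = aggregate_islands(np.array([True]), SMALL, "c")
        out = score_and_filter(isl, {"c": np.array([5])}, 1.0, SMALL)
        assert out[0].score == pytest.approx(1 + np.log(120), rel=1e-12)

    def test_unenriched_island_filtered(self):
        g = Genome({"c": 400})
        params = IslandCallParams(window_p=0.999, effective_genome_fraction=1.0)
        isl = aggregate_islands(np.array([True, True]), params, "c")
        out = score_and_filter(isl, {"c": np.array([1, 1])}, 1.0, params)
        # P(X >= 2 | 2) ~ 0.594: never passes FDR 0.01
        assert out == []

    def test_empty_candidates(self):
        assert score_and_filter([], {}, 1.0, SMALL) == []


class TestFullCaller:
    def test_default_params_match_standard_settings(self):
        p = IslandCallParams()
        assert (p.window_size, p.gap_size, p.fragment_size, p.fdr_threshold) == (
            200, 600, 260, 0.01,
        )

    def test_zero_fragments_error(self):
        with pytest.raises(ValueError):
            call_islands([], Genome({"chr1": 10_000}), SMALL)

    def test_planted_region_recovered(self):
        rng = np.random.default_rng(11)
        g = Genome({"chr1": 40_000})
        frags = []
        for _ in range(int(0.5 * 40_000 / 100)):  # background 5/kb
            frags.append(Fragment("chr1", int(rng.integers(0, 40_000)), "+", 36))
        for _ in range(int(50 * 20 )):  # 20 kb at 50/kb inside [10k, 30k)
            frags.append(Fragment("chr1", int(rng.integers(10_000, 30_000)), "+", 36))
        islands = call_islands(frags, g, SMALL)
        overlapping = [i for i in islands if i.start < 30_000 and i.end > 10_000]
        assert len(overlapping) == 1
        isl = overlapping[0]
        covered = min(isl.end, 30_000) - max(isl.start, 10_000)
        assert covered >= 0.95 * 20_000

    def test_monotone_in_fdr_threshold(self, rng):
        g = Genome({"chr1": 20_000})
        frags = [
            Fragment("chr1", int(rng.integers(0, 20_000)), "+", 36) for _ in range(600)
        ] + [Fragment("chr1", int(rng.integers(5_000, 7_000)), "+", 36) for _ in range(150)]
        loose = call_islands(frags, g, IslandCallParams(
            fdr_threshold=0.5, window_p=0.2, effective_genome_fraction=1.0))
        strict = call_islands(frags, g, IslandCallParams(
            fdr_threshold=0.01, window_p=0.2, effective_genome_fraction=1.0))
        strict_spans = {(i.chrom, i.start, i.end) for i in strict}
        loose_spans = {(i.chrom, i.start, i.end) for i in loose}
        assert strict_spans <= loose_spans

    def test_output_sorted_disjoint_window_aligned(self, rng):
        g = Genome({"chr1": 30_000, "chr2": 10_000})
        frags = [
            Fragment(
                str(rng.choice(["chr1", "chr2"])),
                int(rng.integers(0, 10_000)),
                str(rng.choice(["+", "-"])),
                36,
            )
            for _ in range(2_000)
        ]
        islands = call_islands(frags, g, SMALL)
        for chrom in ("chr1", "chr2"):
            spans = [(i.start, i.end) for i in islands if i.chrom == chrom]
            assert spans == sorted(spans)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
            for s, e in spans:
                assert s % 200 == 0
                assert e % 200 == 0 or e == g.length(chrom)

    def test_matches_independent_oracle(self, rng):
        """Full-caller equivalence with the scan oracle on random toy genomes."""
        params = IslandCallParams(
            window_size=100, gap_size=300, fragment_size=100,
            fdr_threshold=0.05, window_p=0.2, effective_genome_fraction=1.0,
        )
        for _ in range(40):
            n_chrom = int(rng.integers(1, 3))
            genome = Genome(
                {f"c{i}": int(rng.integers(500, 5_000)) for i in range(n_chrom)}
            )
            frags = [
                Fragment(
                    f"c{int(rng.integers(0, n_chrom))}",
                    int(rng.integers(0, 400)) * 10,
                    str(rng.choice(["+", "-"])),
                    36,
                )
                for _ in range(int(rng.integers(1, 250)))
            ]
            frags = [f for f in frags if f.five_prime < genome.length(f.chrom)]
            if not frags:
                continue
            got = sorted(
                (i.chrom, i.start, i.end, i.score, i.fdr_q)
                for i in call_islands(frags, genome, params)
            )
            want = oracle_call_islands(frags, genome, params)
            assert len(got) == len(want)
            for g_, w in zip(got, want):
                assert g_[:3] == w[:3]
                assert g_[3] == pytest.approx(w[3], abs=1e-9)
                assert g_[4] == pytest.approx(w[4], abs=1e-9)
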