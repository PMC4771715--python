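import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cotarget.cooccupancy import (
    Peak,
    VennCounts,
    format_pvalue,
    match_overlapping_peaks,
    score_peaks,
    spearman_correlation,
    venn_decompose,
)
from cotarget.coverage import CoverageTrack, peak_intensity, read_bedgraph, write_bedgraph
from cotarget.intervals import GenomicInterval

from conftest import brute_interval_sum, brute_spearman_rho

iv = GenomicInterval


class TestPeakIntensity:
    def test_uniform_coverage(self):
        cov = CoverageTrack({"chr1": [(0, 1000, 2.0)]})
        assert peak_intensity(iv("chr1", 100, 200), cov) == 200.0

    def test_zero_coverage_and_absent_chromosome(self):
        cov = CoverageTrack({"chr1": [(0, 10, 5.0)]})
        assert peak_intensity(iv("chr1", 100, 200), cov) == 0.0
        assert peak_intensity(iv("chr2", 0, 10), cov) == 0.0

    def test_segment_straddling_peak(self):
        cov = CoverageTrack({"chr1": [(0, 12, 3.0), (12, 20, 1.0)]})
        # per-base: 3+3+1+1+1
        assert peak_intensity(iv("chr1", 10, 15), cov) == 9.0

    def test_matches_per_base_loop_on_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pos, segs = 0, []
            for _ in range(rng.integers(1, 8)):
                pos += int(rng.integers(0, 5))
                width = int(rng.integers(1, 10))
                segs.append((pos, pos + width, float(rng.integers(0, 6))))
                pos += width
            cov = CoverageTrack({"chr1": segs})
            for _ in range(4):
                start = int(rng.integers(0, pos + 5))
                end = start + int(rng.integers(1, 15))
                peak = iv("chr1", start, end)
                assert peak_intensity(peak, cov) == brute_interval_sum(
                    cov, "chr1", start, end
                )

    def test_overlapping_coverage_segments_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            CoverageTrack({"chr1": [(0, 10, 1.0), (5, 15, 2.0)]})

    def test_bedgraph_round_trip(self, tmp_path):
        cov = CoverageTrack({"chr1": [(0, 12, 3.0), (12, 20, 1.0)], "chr2": [(5, 9, 2.5)]})
        p = tmp_path / "c.bedgraph"
        write_bedgraph(cov, p)
        back = read_bedgraph(p)
        for chrom in cov.chroms:
            assert back.segments(chrom) == cov.segments(chrom)


class TestVennDecompose:
    def test_disjoint_sets(self):
        a = [iv("chr1", 0, 10)]
        b = [iv("chr1", 100, 110)]
        v = venn_decompose(a, b)
        assert v.a_overlapping_b == 0 and v.b_overlapping_a == 0

    def test_identical_sets(self):
        peaks = [iv("chr1", i * 100, i * 100 + 50) for i in range(5)]
        v = venn_decompose(peaks, peaks)
        assert v.a_overlapping_b == v.b_overlapping_a == 5

    def test_one_a_peak_counted_once_despite_two_b_overlaps(self):
        a = [iv("chr1", 0, 100)]
        b = [iv("chr1", 0, 10), iv("chr1", 50, 60)]
        v = venn_decompose(a, b)
        assert v.a_overlapping_b == 1 and v.b_overlapping_a == 2

    def test_display_percent_rounds_to_nearest(self):
        v = VennCounts(total_a=9941, total_b=13000, a_overlapping_b=6022, b_overlapping_a=6022)
        assert v.fraction_a == pytest.approx(0.60577, abs=1e-4)
        assert v.percent_a == 61

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(7)
        peaks_a = [iv("chr1", int(s), int(s) + 30) for s in rng.integers(0, 5000, 40)]
        peaks_b = [iv("chr1", int(s), int(s) + 30) for s in rng.integers(0, 5000, 40)]
        v1 = venn_decompose(peaks_a, peaks_b)
        v2 = venn_decompose(
            [peaks_a[i] for i in rng.permutation(40)],
            [peaks_b[i] for i in rng.permutation(40)],
        )
        assert v1 == v2


class TestMatchOverlappingPeaks:
    def test_maximal_shared_bases_wins(self):
        a = [Peak(iv("chr1", 0, 10), "A", 1.0)]
        b1 = Peak(iv("chr1", 8, 20), "B", 2.0)   # 2 shared
        b2 = Peak(iv("chr1", 0, 6), "B", 3.0)    # 6 shared
        pairs = match_overlapping_peaks(a, [b1, b2])
        assert pairs == [(a[0], b2)]

    def test_no_overlaps_empty(self):
        a = [Peak(iv("chr1", 0, 10), "A", 1.0)]
        b = [Peak(iv("chr2", 0, 10), "B", 1.0)]
        assert match_overlapping_peaks(a, b) == []

    def test_tie_broken_by_leftmost_b(self):
        a = [Peak(iv("chr1", 10, 20), "A", 1.0)]
        b1 = Peak(iv("chr1", 5, 15), "B", 1.0)   # 5 shared
        b2 = Peak(iv("chr1", 15, 25), "B", 1.0)  # 5 shared
        pairs = match_overlapping_peaks(a, [b2, b1])
        assert pairs == [(a[0], b1)]

    def test_one_to_one_and_deterministic(self):
        rng = np.random.default_rng(3)
        a = [Peak(iv("chr1", int(s), int(s) + 40), "A", float(i))
             for i, s in enumerate(rng.integers(0, 3000, 30))]
        b = [Peak(iv("chr1", int(s), int(s) + 40), "B", float(i))
             for i, s in enumerate(rng.integers(0, 3000, 30))]
        p1 = match_overlapping_peaks(a, b)
        p2 = match_overlapping_peaks(a, b)
        assert p1 == p2
        assert len({id(x) for x, _ in p1}) == len(p1)
        assert len({id(y) for _, y in p1}) == len(p1)

    def test_scoring_attaches_intensities(self):
        cov = CoverageTrack({"chr1": [(0, 100, 2.0)]})
        scored = score_peaks([iv("chr1", 0, 50)], cov, "A")
        assert scored[0].intensity == 100.0
        assert scored[0].factor == "A"


finite_floats = st.floats(-1e6, 1e6, allow_nan=False)


class TestSpearman:
    def test_identical_order_is_one(self):
        rho, _ = spearman_correlation([1, 5, 9], [1, 5, 9])
        assert rho == pytest.approx(1.0)

    def test_reversed_order_is_minus_one(self):
        rho, _ = spearman_correlation([1, 5, 9], [9, 5, 1])
        assert rho == pytest.approx(-1.0)

    def test_three_point_example(self):
        # d = (2, 1, 1): rho = 1 - 6*6/(3*8) = -0.5; every permutation of
        # three distinct ranks has |rho| >= 0.5, so the exact p is 1.
        rho, p = spearman_correlation([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)
        assert p == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_matches_brute_force_rank_oracle_including_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            # integer draws force ties
            x = rng.integers(0, max(2, n // 2), n).astype(float)
            y = rng.integers(0, max(2, n // 2), n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = spearman_correlation(x, y)
            assert rho == pytest.approx(brute_spearman_rho(x, y), abs=1e-12)

    def test_matches_scipy_rho_and_large_n_pvalue(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        rho, p = spearman_correlation(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_permutation_p_matches_enumeration(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = spearman_correlation(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            hits += abs(r) >= abs(rho) - 1e-12
        assert p == pytest.approx(hits / total, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(finite_floats, min_size=12, max_size=25, unique=True))
    def test_invariant_under_monotone_transform(self, x):
        rng = np.random.default_rng(len(x))
        y = rng.normal(size=len(x))
        xa = np.asarray(x)
        rho1, p1 = spearman_correlation(xa, y)
        # x**3 + x is strictly increasing and keeps distinct floats distinct
        rho2, p2 = spearman_correlation(xa**3 + xa, y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_pvalue_display_floor(self):
        assert format_pvalue(1e-30) == "< 2.2e-16"
        assert format_pvalue(0.0123) == "0.0123"
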