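"""Height binning, trend regressions, KS comparisons and subsampling."""

import numpy as np
import pytest
from scipy import stats

from peakspec.intervals import GenomicInterval, Peak, PeakSet
from peakspec.trends import (
    bin_by_height,
    bin_trend,
    cofactor_pwm_ks,
    expression_peakcount_correlation,
    extreme_height_comparison,
    gc_balanced_subset,
    median_diff_by_height,
)


def make_peaks(heights, tf="t", cell="c"):
    return PeakSet(
        [
            Peak(GenomicInterval("chr1", 1000 * i, 1000 * i + 100), int(h), tf, cell, f"p{i:04d}")
            for i, h in enumerate(heights)
        ]
    )


class TestBinByHeight:
    def test_exact_division(self):
        b = bin_by_height(make_peaks(range(1, 101)), 10)
        sizes = [len(m) for m in b.bin_members()]
        assert sizes == [10] * 10

    def test_remainder_goes_to_highest_bins(self):
        b = bin_by_height(make_peaks(range(103)), 10)
        sizes = [len(m) for m in b.bin_members()]
        assert sizes == [10] * 7 + [11] * 3

    def test_bins_ordered_by_height(self):
        heights = np.random.default_rng(3).integers(1, 1000, size=95)
        ps = make_peaks(heights)
        b = bin_by_height(ps, 10)
        hmap = {p.peak_id: p.height for p in ps}
        maxes = [max(hmap[pid] for pid in m) for m in b.bin_members()]
        mins = [min(hmap[pid] for pid in m) for m in b.bin_members()]
        assert all(maxes[i] <= mins[i + 1] for i in range(9))
        # concatenating bins recovers a height-sorted permutation
        concat = [hmap[pid] for m in b.bin_members() for pid in sorted(
            m, key=lambda pid: (hmap[pid], pid))]
        assert concat == sorted(heights.tolist())

    def test_tie_determinism(self):
        ps = make_peaks([5] * 30)
        b1 = bin_by_height(ps, 10)
        b2 = bin_by_height(ps, 10)
        assert b1.assignments == b2.assignments

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            bin_by_height(make_peaks([1, 2, 3]), 10)


class TestBinTrend:
    def test_perfect_line(self):
        ps = make_peaks(range(100))
        b = bin_by_height(ps, 10)
        values = {pid: float(idx) for pid, idx in b.assignments.items()}
        res = bin_trend(b, values)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.p_value < 1e-6 and res.significant

    def test_matches_hand_ols_on_bin_means(self):
        ps = make_peaks(range(100))
        b = bin_by_height(ps, 10)
        rng = np.random.default_rng(0)
        values = {pid: float(rng.normal(idx, 0.5)) for pid, idx in b.assignments.items()}
        res = bin_trend(b, values)
        x = np.arange(1, 11, dtype=float)
        y = np.array(res.bin_means)
        fit = stats.linregress(x, y)
        assert res.slope == pytest.approx(fit.slope, abs=1e-12)
        assert res.p_value == pytest.approx(fit.pvalue, abs=1e-12)

    def test_constant_feature_is_degenerate(self):
        ps = make_peaks(range(100))
        b = bin_by_height(ps, 10)
        res = bin_trend(b, {pid: 1.0 for pid in b.assignments})
        assert res.degenerate and res.slope == 0.0 and res.p_value == 1.0

    def test_null_rejection_rate_near_alpha(self):
        """Type-I error of the slope test on height-independent features."""
        n_sims, n_peaks, rejections = 120, 300, 0
        ps = make_peaks(np.random.default_rng(5).integers(1, 500, size=n_peaks))
        b = bin_by_height(ps, 10)
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            values = {pid: float(v) for pid, v in zip(b.assignments, rng.normal(size=n_peaks))}
            if bin_trend(b, values).significant:
                rejections += 1
        rate = rejections / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < 3.5 * se


class TestGcBalancedSubset:
    def test_single_gc_bin_keeps_trimmed_input(self):
        ps = make_peaks(range(100))
        b = bin_by_height(ps, 10)
        gc = {p.peak_id: 0.5 for p in ps}
        out = gc_balanced_subset(ps, gc, b, seed=1)
        assert len(out) == 100  # identical GC: no trimming possible, all kept

    def test_min_count_rule(self):
        ps = make_peaks([1] * 40)
        b = bin_by_height(ps, 1)
        ids = sorted(p.peak_id for p in ps)
        gc = {pid: (0.3 if i < 30 else 0.7) for i, pid in enumerate(ids)}
        out = gc_balanced_subset(ps, gc, b, n_gc_bins=2, trim=0.0, seed=1)
        got = {0.3: 0, 0.7: 0}
        for p in out:
            got[gc[p.peak_id]] += 1
        assert got[0.3] == got[0.7] == 10

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        ps = make_peaks(rng.integers(1, 100, size=200))
        gc = {p.peak_id: float(rng.uniform(0.2, 0.8)) for p in ps}
        b = bin_by_height(ps, 10)
        out1 = gc_balanced_subset(ps, gc, b, seed=42)
        out2 = gc_balanced_subset(ps, gc, b, seed=42)
        assert [p.peak_id for p in out1] == [p.peak_id for p in out2]

    def test_homogenizes_confounded_gc(self):
        """A planted GC-height confound disappears after balancing."""
        rng = np.random.default_rng(9)
        heights = np.arange(1, 501)
        ps = make_peaks(heights)
        gc = {
            p.peak_id: float(np.clip(rng.normal(0.4 + 0.15 * p.height / 500, 0.1), 0, 1))
            for p in ps
        }
        b = bin_by_height(ps, 5)
        out = gc_balanced_subset(ps, gc, b, n_gc_bins=5, seed=3)
        hmap = {p.peak_id: p.height for p in ps}

        def mean_gap(peaks):
            lo = [gc[p.peak_id] for p in peaks if hmap[p.peak_id] <= 250]
            hi = [gc[p.peak_id] for p in peaks if hmap[p.peak_id] > 250]
            return abs(np.mean(lo) - np.mean(hi))

        # balancing shrinks the GC gap between height halves substantially
        assert mean_gap(out) < mean_gap(list(ps)) / 3


class TestExtremeHeightComparison:
    def _inputs(self, n=200, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ps = make_peaks(rng.integers(1, 1000, size=n))
        labels = {p.peak_id: ("specific" if i % 2 else "common")
                  for i, p in enumerate(ps)}
        own = {p.peak_id: float(rng.normal(shift if labels[p.peak_id] == "specific" else 0, 1))
               for p in ps}
        other = {p.peak_id: float(rng.normal(0, 1)) for p in ps}
        return list(ps), labels, own, other

    def test_identical_distributions(self):
        peaks, labels, own, _ = self._inputs()
        res = extreme_height_comparison(peaks, labels, own, own, side="highest")
        spec = next(r for r in res if r.group == "specific")
        assert spec.statistic == 0.0 and spec.p_value == 1.0

    def test_disjoint_supports(self):
        peaks, labels, own, other = self._inputs()
        shifted = {k: v + 100 for k, v in own.items()}
        res = extreme_height_comparison(peaks, labels, shifted, other, side="lowest")
        spec = next(r for r in res if r.group == "specific")
        assert spec.statistic == 1.0

    def test_power_under_elevation(self):
        hits = 0
        for seed in range(10):
            peaks, labels, own, other = self._inputs(n=500, shift=1.0, seed=seed)
            res = extreme_height_comparison(peaks, labels, own, other, side="highest")
            spec = next(r for r in res if r.group == "specific")
            if spec.p_value < 0.05:
                hits += 1
        assert hits >= 9

    def test_invalid_side_rejected(self):
        peaks, labels, own, other = self._inputs()
        with pytest.raises(ValueError):
            extreme_height_comparison(peaks, labels, own, other, side="middle")


class TestMedianDiffByHeight:
    def test_zero_when_equal(self):
        ps = make_peaks(range(100))
        b = bin_by_height(ps, 10)
        own = {pid: 1.0 for pid in b.assignments}
        assert median_diff_by_height(b, own, own) == [0.0] * 10

    def test_increasing_construction(self):
        ps = make_peaks(range(100))
        b = bin_by_height(ps, 10)
        other = {pid: 1.0 for pid in b.assignments}
        own = {pid: 1.0 + idx for pid, idx in b.assignments.items()}
        diffs = median_diff_by_height(b, own, other)
        assert diffs == sorted(diffs)
        assert diffs[0] == pytest.approx(0.0)
        assert diffs[9] == pytest.approx(9.0)

    def test_matches_brute_force(self, rng):
        ps = make_peaks(rng.integers(1, 100, size=97))
        b = bin_by_height(ps, 10)
        own = {pid: float(rng.normal()) for pid in b.assignments}
        other = {pid: float(rng.normal()) for pid in b.assignments}
        got = median_diff_by_height(b, own, other)
        for bi, members in enumerate(b.bin_members()):
            expected = np.median([own[p] for p in members]) - np.median(
                [other[p] for p in members]
            )
            assert got[bi] == pytest.approx(expected, abs=1e-12)


class TestCofactorKs:
    def test_identical_samples(self):
        d, _ = cofactor_pwm_ks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=100), rng.normal(0.5, 1, size=120)
        d, p = cofactor_pwm_ks(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
        # small samples switch to the exact distribution
        a2, b2 = rng.normal(size=15), rng.normal(size=20)
        ref2 = stats.ks_2samp(a2, b2, method="exact")
        assert cofactor_pwm_ks(a2, b2)[1] == pytest.approx(ref2.pvalue)

    def test_shift_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=200)
            b = rng.normal(1.0, 1, size=200)
            if cofactor_pwm_ks(a, b)[1] < 0.05:
                hits += 1
        assert hits == 10

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            cofactor_pwm_ks([1.0], [1.0, 2.0])


class TestExpressionPeakcountCorrelation:
    def test_proportional_gives_r_one(self):
        tfs = [f"T{i}" for i in range(6)]
        expr_a = {t: float(i + 1) for i, t in enumerate(tfs)}
        expr_b = {t: 1.0 for t in tfs}
        count_a = {t: 10 * (i + 1) for i, t in enumerate(tfs)}
        count_b = {t: 10 for t in tfs}
        res = expression_peakcount_correlation(expr_a, expr_b, count_a, count_b)
        assert res.r == pytest.approx(1.0)

    def test_outlier_removal_raises_correlation(self):
        tfs = [f"T{i}" for i in range(8)]
        expr_a = {t: float(i + 1) for i, t in enumerate(tfs)}
        expr_b = {t: 1.0 for t in tfs}
        count_a = {t: 10 * (i + 1) for i, t in enumerate(tfs)}
        count_b = {t: 10 for t in tfs}
        expr_a["T7"] = 0.01  # planted outlier against the count trend
        res = expression_peakcount_correlation(
            expr_a, expr_b, count_a, count_b, exclude={"T7"}
        )
        assert res.r_excluded > res.r

    def test_too_few_tfs_rejected(self):
        with pytest.raises(ValueError):
            expression_peakcount_correlation({"a": 1}, {"a": 1}, {"a": 1}, {"a": 1})
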