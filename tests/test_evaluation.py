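"""Correlation metric, rescaling, histogram and rank-sum statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xasurrogate.evaluation import (
    band_power_fraction,
    compare_methods,
    comparison_matrix,
    corr_histogram,
    correlation,
    rescale_overlay,
    summarize,
)


def brute_force_ranksum_p(a, b):
    """Independent enumeration oracle for the one-tailed exact mid-p.

    Pools the samples, ranks by sorting (midranks for ties), and walks
    every assignment of group labels via bitmasks -- no shared code with
    the implementation beyond numpy sorting.
    """
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # midrank
        i = j + 1
    observed = ranks[: len(a)].sum()
    n = len(pooled)
    gt = eq = total = 0
    for bits in range(1 << n):
        if bin(bits).count("1") != len(a):
            continue
        s = sum(ranks[k] for k in range(n) if bits >> k & 1)
        if s > observed + 1e-12:
            gt += 1
        elif abs(s - observed) <= 1e-12:
            eq += 1
        total += 1
    return (gt + 0.5 * eq) / total


class TestCorrelation:
    def test_self_correlation(self):
        assert correlation([1.0, 2.0, 3.0, 4.0], [1, 2, 3, 4]) == 1.0

    def test_affine_and_sign_invariance(self):
        t = np.array([1.0, 2.0, 2.0, 4.0])
        assert correlation(-2 * t + 7, t) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # p=[1,2,3,4], t=[1,2,2,4]: centered products sum to 4.5,
        # sum of squares 5 and 4.75, so r = 4.5/sqrt(5*4.75)
        r = correlation([1, 2, 3, 4], [1, 2, 2, 4])
        assert r == pytest.approx(4.5 / np.sqrt(23.75), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlation([1.0, 1.0, 1.0], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            correlation([1, 2, 3], [1, 2, 3, 4])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.floats(-5, 5).filter(lambda s: abs(s) > 1e-3),
        st.floats(-100, 100),
    )
    def test_invariant_under_affine_maps(self, slope, intercept):
        rng = np.random.default_rng(7)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        r0 = correlation(a, b)
        r1 = correlation(slope * a + intercept, b)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestRescaleOverlay:
    def test_endpoint_mapping(self):
        np.testing.assert_allclose(
            rescale_overlay([0.0, 1.0], 10, 20), [10.0, 20.0]
        )

    def test_targets_hit_exactly(self, rng):
        out = rescale_overlay(rng.normal(size=50), -3.5, 8.25)
        assert out.min() == pytest.approx(-3.5)
        assert out.max() == pytest.approx(8.25)

    def test_orientation_follows_truth(self):
        p = np.array([3.0, 2.0, 1.0])
        truth = np.array([1.0, 2.0, 3.0])
        out = rescale_overlay(p, 0, 1, truth=truth)
        assert np.corrcoef(out, truth)[0, 1] > 0

    def test_preserves_absolute_correlation(self, rng):
        p = rng.normal(size=30)
        ref = rng.normal(size=30)
        out = rescale_overlay(p, 100, 200)
        assert correlation(out, ref) == pytest.approx(correlation(p, ref))

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rescale_overlay([2.0, 2.0, 2.0], 0, 1)


class TestHistogram:
    def test_default_bins(self):
        np.testing.assert_array_equal(
            corr_histogram([0.95, 0.92, 0.85]), [0, 1, 2]
        )

    def test_counts_conserved(self, rng):
        rs = rng.uniform(0, 1, 37)
        assert corr_histogram(rs).sum() == 37

    def test_empty_input(self):
        np.testing.assert_array_equal(corr_histogram([]), [0, 0, 0])

    def test_top_bin_right_closed(self):
        np.testing.assert_array_equal(corr_histogram([1.0, 0.9]), [0, 0, 2])


class TestRankSum:
    def test_identical_samples_give_half(self):
        rs = [0.91, 0.87, 0.95, 0.83]
        assert compare_methods(rs, rs) == pytest.approx(0.5)

    def test_fully_separated_samples(self):
        # all 20 assignments enumerated; the observed rank sum is the
        # unique maximum, so the mid-p is half its point mass: 1/40
        p = compare_methods([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(brute_force_ranksum_p(
            np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0])
        ))
        assert p == pytest.approx(1.0 / 40.0)

    def test_swap_antisymmetry(self, rng):
        a = rng.uniform(0, 1, 4)
        b = rng.uniform(0, 1, 4)
        assert compare_methods(a, b) + compare_methods(b, a) == (
            pytest.approx(1.0)
        )

    def test_exact_path_matches_brute_force(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 1, 4)
            b = rng.uniform(0, 1, 4)
            assert compare_methods(a, b) == pytest.approx(
                brute_force_ranksum_p(a, b), abs=1e-12
            )

    def test_exact_path_with_ties(self):
        a = np.array([0.9, 0.9, 0.8])
        b = np.array([0.8, 0.7, 0.7])
        assert compare_methods(a, b) == pytest.approx(
            brute_force_ranksum_p(a, b)
        )

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        a = rng.normal(1.0, 0.1, 12)
        b = rng.normal(0.0, 0.1, 12)
        p = compare_methods(a, b)
        ref = stats.mannwhitneyu(
            a, b, alternative="greater", method="asymptotic",
            use_continuity=False,
        ).pvalue
        assert p == pytest.approx(float(ref))
        assert p < 0.01

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_methods([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSummary:
    def test_two_value_group(self):
        table = summarize(
            [{"method": "m", "scope": "mono", "r": 0.9},
             {"method": "m", "scope": "mono", "r": 1.0}]
        )
        row = table.iloc[0]
        assert row["n"] == 2
        assert row["mean"] == pytest.approx(0.95)
        assert row["std"] == pytest.approx(np.sqrt(0.005))

    def test_single_value_group_flagged_by_n(self):
        table = summarize([{"method": "m", "scope": "mono", "r": 0.8}])
        assert table.iloc[0]["n"] == 1
        assert table.iloc[0]["std"] == 0.0

    def test_column_order_contract(self):
        table = summarize([{"method": "m", "scope": "mono", "r": 0.8}])
        assert list(table.columns) == ["method", "scope", "n", "mean", "std"]

    def test_comparison_matrix_layout(self, rng):
        rs = {
            "a": rng.uniform(0.8, 1.0, 5),
            "b": rng.uniform(0.5, 0.9, 5),
        }
        mat = comparison_matrix(rs)
        assert np.isnan(mat.loc["a", "a"])
        assert mat.loc["a", "b"] + mat.loc["b", "a"] == pytest.approx(1.0)


class TestBandPower:
    def test_on_bin_tone_concentrates_power(self):
        fs, n = 15.0, 120
        f0 = 10 * fs / n  # exactly on a frequency bin
        t = np.arange(n) / fs
        v = np.sin(2 * np.pi * f0 * t)
        assert band_power_fraction(v, fs, f0) > 0.95

    def test_off_bin_tone_still_dominates_band(self):
        fs, n = 15.0, 120
        t = np.arange(n) / fs
        v = np.sin(2 * np.pi * 1.2 * t)  # between bins: spectral leakage
        assert band_power_fraction(v, fs, 1.2) > 0.6

    def test_off_band_tone_has_negligible_power(self):
        fs, n = 15.0, 120
        t = np.arange(n) / fs
        v = np.sin(2 * np.pi * 0.25 * t)
        assert band_power_fraction(v, fs, 1.2) < 0.01
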