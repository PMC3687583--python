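"""Exact binomial marker tests and multi-pool concordance filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bsamap import (QtlRegion, binomial_linkage_test, concordance_filter,
                    evaluate_groups, reciprocal_overlap, score_marker)


class TestBinomialLinkageTest:
    def test_extreme_and_central_counts(self):
        assert binomial_linkage_test(22, 22, "superior") == pytest.approx(0.5 ** 22)
        # central count: tail from the exact Binomial(22, 1/2) mass
        expect = sum(__import__("math").comb(22, i) for i in range(11, 23)) / 2 ** 22
        assert binomial_linkage_test(11, 22, "superior") == pytest.approx(expect)
        assert expect == pytest.approx(0.584, abs=5e-4)

    def test_tail_symmetry_at_zero(self):
        assert binomial_linkage_test(0, 22, "superior") == 1.0
        assert binomial_linkage_test(0, 22, "inferior") == pytest.approx(0.5 ** 22)

    def test_matches_scipy_binomtest_oracle(self):
        for n in range(1, 26):
            for k in range(n + 1):
                assert binomial_linkage_test(k, n, "superior") == pytest.approx(
                    stats.binomtest(k, n, 0.5, alternative="greater").pvalue, abs=1e-12)
                assert binomial_linkage_test(k, n, "inferior") == pytest.approx(
                    stats.binomtest(k, n, 0.5, alternative="less").pvalue, abs=1e-12)

    @given(n=st.integers(1, 60), k=st.integers(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_superior_p_nonincreasing_in_k(self, n, k):
        k = min(k, n)
        p_k = binomial_linkage_test(k, n, "superior")
        assert 0 <= p_k <= 1
        if k > 0:
            assert p_k <= binomial_linkage_test(k - 1, n, "superior")

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_linkage_test(5, 0, "superior")
        with pytest.raises(ValueError):
            binomial_linkage_test(6, 5, "superior")
        with pytest.raises(ValueError):
            binomial_linkage_test(1, 5, "sideways")


class TestScoreMarker:
    def _genotypes(self):
        idx = [f"s{i}" for i in range(22)]
        df = pd.DataFrame({7: ["S"] * 22, 8: ["S"] * 11 + ["I"] * 11}, index=idx)
        df.loc[["s0", "s1", "s2"], 8] = np.nan
        return df

    def test_counts_and_frequency(self):
        g = self._genotypes()
        ms = score_marker(g, 7, g.index, "all")
        assert (ms.k, ms.n, ms.frequency) == (22, 22, 1.0)

    def test_missing_calls_excluded_from_n(self):
        g = self._genotypes()
        ms = score_marker(g, 8, g.index, "all")
        assert ms.n == 19

    def test_unknown_marker_or_strain_is_an_error(self):
        g = self._genotypes()
        with pytest.raises(ValueError):
            score_marker(g, 99, g.index)
        with pytest.raises(ValueError):
            score_marker(g, 7, ["nope"])
        with pytest.raises(ValueError):
            score_marker(g, 7, [])


class TestEvaluateGroups:
    def test_table_shape_and_flags(self):
        idx = [f"s{i}" for i in range(8)]
        g = pd.DataFrame({1: ["S"] * 8, 2: ["S"] * 4 + ["I"] * 4}, index=idx)
        out = evaluate_groups(g, [1, 2], {"grp": idx}, alpha=0.05)
        assert len(out) == 2
        m1 = out[out.marker == 1].iloc[0]
        assert m1.k == 8 and m1.sig_superior == (m1.p_superior < 0.05)

    def test_empty_marker_list_gives_empty_table(self):
        g = pd.DataFrame({1: ["S"]}, index=["s0"])
        assert evaluate_groups(g, [], {"grp": ["s0"]}).empty

    def test_undefined_group_is_an_error(self):
        g = pd.DataFrame({1: ["S"]}, index=["s0"])
        with pytest.raises(ValueError):
            evaluate_groups(g, [1], {"grp": []})

    def test_type1_error_rate_near_alpha(self):
        """Unlinked marker in a group of 22: the rate of a false linkage
        call in either direction sits near alpha over 1,000 nulls."""
        rng = np.random.default_rng(77)
        alpha = 0.05
        false = 0
        reps = 1_000
        for _ in range(reps):
            k = rng.binomial(22, 0.5)
            false += (binomial_linkage_test(k, 22, "superior") < alpha
                      or binomial_linkage_test(k, 22, "inferior") < alpha)
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(false / reps - alpha) < 3 * se


def _region(chrom, start, end, direction="superior", pool="p"):
    return QtlRegion(chrom=chrom, start=start, end=end, direction=direction,
                     mean_posterior=0.99, n_markers=5, pool_id=pool)


class TestConcordanceFilter:
    def test_single_pool_region_is_rejected(self):
        sets = [[_region(1, 100, 200, pool="a")], [], []]
        assert concordance_filter(sets, [], min_pools=2) == []

    def test_replicated_region_retained_with_intersection(self):
        sets = [[_region(1, 100, 220, pool="a")],
                [_region(1, 150, 260, pool="b")],
                [_region(1, 120, 240, pool="c")]]
        out = concordance_filter(sets, [], min_pools=2)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (150, 220)

    def test_region_also_in_unselected_pool_is_rejected(self):
        sets = [[_region(1, 100, 200, pool="a")], [_region(1, 110, 210, pool="b")], []]
        uns = [_region(1, 180, 300, pool="uns")]
        assert concordance_filter(sets, uns, min_pools=2) == []
        # opposite-direction unselected region does not veto
        uns_flip = [_region(1, 180, 300, "inferior", "uns")]
        assert len(concordance_filter(sets, uns_flip, min_pools=2)) == 1

    def test_direction_must_be_concordant(self):
        sets = [[_region(1, 100, 200, "superior", "a")],
                [_region(1, 100, 200, "inferior", "b")], []]
        assert concordance_filter(sets, [], min_pools=2) == []

    def test_nested_narrow_interval_supports_wide_one(self):
        # an advanced-generation pool calls a narrow interval inside an F1 call
        sets = [[_region(1, 100_000, 160_000, pool="f1")],
                [_region(1, 120_000, 128_000, pool="f5")]]
        out = concordance_filter(sets, [], min_pools=2)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (120_000, 128_000)

    def test_min_pools_exceeding_sets_is_an_error(self):
        with pytest.raises(ValueError):
            concordance_filter([[]], [], min_pools=2)

    def test_never_retains_unsupported_region(self, rng):
        """Brute-force oracle: every validated interval must lie inside a
        region that finds >= min_pools same-direction overlapping
        supporters among the selected sets."""
        for _ in range(20):
            sets = []
            for p in range(3):
                regions = []
                for _ in range(rng.integers(0, 5)):
                    s = int(rng.integers(1, 500_000))
                    regions.append(_region(int(rng.integers(1, 3)), s,
                                           s + int(rng.integers(1_000, 80_000)),
                                           rng.choice(["superior", "inferior"]),
                                           f"p{p}"))
                sets.append(regions)
            validated = concordance_filter(sets, [], min_pools=2)
            for v in validated:
                n_support = 0
                for region_set in sets:
                    n_support += any(
                        r.direction == v.direction and r.chrom == v.chrom
                        and min(r.end, v.end) >= max(r.start, v.start)
                        for r in region_set)
                assert n_support >= 2

    def test_reciprocal_overlap_is_symmetric_fraction_of_longer(self):
        a, b = _region(1, 100, 199), _region(1, 150, 449)
        assert reciprocal_overlap(a, b) == pytest.approx(50 / 300)
        assert reciprocal_overlap(b, a) == reciprocal_overlap(a, b)
        assert reciprocal_overlap(a, _region(2, 100, 199)) == 0.0
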