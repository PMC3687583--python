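"""Smoothing and binomial-emission HMM segmentation."""

import numpy as np
import pytest

from bsamap import (HmmParams, build_pool, call_regions, hmm_posteriors,
                    sample_read_counts, smooth_track, variant_frequency)
from bsamap.poolseq import PoolCounts, VariantFrequencyTrack
from bsamap.qtl_map import STATE_INFERIOR, STATE_SUPERIOR

from hmm_oracle import enumerate_posteriors, random_instance


def _track(pos, freq, cov, chrom=None):
    pos = np.asarray(pos)
    chrom = np.ones(len(pos), dtype=int) if chrom is None else np.asarray(chrom)
    return VariantFrequencyTrack(chrom=chrom, pos=pos, freq=np.asarray(freq, float),
                                 coverage=np.asarray(cov))


def _counts(k, n, pos, chrom=None, pool="t"):
    pos = np.asarray(pos)
    chrom = np.ones(len(pos), dtype=int) if chrom is None else np.asarray(chrom)
    return PoolCounts(pool_id=pool, chrom=chrom, pos=pos, k=k, n=n)


class TestSmoothing:
    def test_constant_track_is_preserved(self):
        t = _track(np.arange(1, 2001, 100), np.full(20, 0.37), np.full(20, 50))
        s = smooth_track(t, bandwidth=500)
        assert np.allclose(s.smoothed, 0.37)
        assert np.all(s.lower <= s.smoothed) and np.all(s.smoothed <= s.upper)

    def test_single_covered_marker_equals_raw(self):
        t = _track([100, 5000], [0.8, np.nan], [40, 0])
        s = smooth_track(t, bandwidth=1000)
        assert s.smoothed[0] == pytest.approx(0.8)
        assert np.isnan(s.smoothed[1])   # no covered marker within the window

    def test_matches_direct_summation_oracle(self, rng):
        pos = np.sort(rng.choice(100_000, size=60, replace=False)) + 1
        cov = rng.poisson(50, 60)
        freq = np.where(cov > 0, rng.random(60), np.nan)
        t = _track(pos, freq, cov)
        bw = 8_000.0
        s = smooth_track(t, bandwidth=bw)
        for i in range(60):      # independent brute-force weighted mean
            num = den = 0.0
            for j in range(60):
                d = abs(float(pos[j]) - float(pos[i]))
                if cov[j] > 0 and d <= bw:
                    w = (1 - (d / bw) ** 3) ** 3 * cov[j]
                    num += w * freq[j]
                    den += w
            if den > 0:
                assert abs(s.smoothed[i] - num / den) < 1e-12
            else:
                assert np.isnan(s.smoothed[i])

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(_track([1], [0.5], [10]), bandwidth=0)


class TestHmmPosteriors:
    def test_uncovered_single_marker_returns_prior(self):
        params = HmmParams()
        post = hmm_posteriors(_counts([0], [0], [100]), params)
        assert np.allclose(post[0], params.priors)

    def test_posteriors_normalise(self, rng):
        k, n, pos = random_instance(rng, max_markers=8)
        post = hmm_posteriors(_counts(k, n, pos), HmmParams())
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        params = HmmParams(p_link=0.85, persistence_bp=15_000,
                           priors=(0.9, 0.06, 0.04))
        for _ in range(50):
            k, n, pos = random_instance(rng)
            post = hmm_posteriors(_counts(k, n, pos), params)
            oracle = enumerate_posteriors(k, n, pos, params)
            assert np.max(np.abs(post - oracle)) < 1e-10

    def test_mirror_symmetry_swaps_directions(self, rng):
        k = rng.integers(0, 101, size=80)
        n = np.full(80, 100)
        pos = np.arange(1, 81) * 2_000
        post = hmm_posteriors(_counts(k, n, pos), HmmParams())
        flipped = hmm_posteriors(_counts(n - k, n, pos), HmmParams())
        assert np.allclose(post[:, STATE_SUPERIOR], flipped[:, STATE_INFERIOR], atol=1e-12)
        assert np.allclose(post[:, 0], flipped[:, 0], atol=1e-12)

    def test_neutral_track_yields_no_call(self):
        params = HmmParams()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = rng.poisson(100, 200)
            k = rng.binomial(n, 0.5)
            counts = _counts(k, n, np.arange(1, 201) * 2_000)
            post = hmm_posteriors(counts, params)
            linked = np.maximum(post[:, STATE_SUPERIOR], post[:, STATE_INFERIOR])
            assert np.all(linked < params.posterior_threshold)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HmmParams(p_link=0.4)
        with pytest.raises(ValueError):
            HmmParams(priors=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            HmmParams(persistence_bp=0)


class TestCallRegions:
    def _planted_counts(self, seed, block_freq, block=(200_000, 240_000), m=300,
                        chrom_len=600_000, depth=100):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(chrom_len, size=m, replace=False)) + 1
        f = np.where((pos >= block[0]) & (pos <= block[1]), block_freq, 0.5)
        n = rng.poisson(depth, m)
        k = rng.binomial(n, f)
        return _counts(k, n, pos)

    def test_no_posterior_above_threshold_gives_empty_list(self):
        counts = _counts([50, 49, 51], [100, 100, 100], [1000, 3000, 5000])
        params = HmmParams()
        assert call_regions(hmm_posteriors(counts, params), counts, params) == []

    @pytest.mark.parametrize("block_freq,direction", [(0.95, "superior"),
                                                      (0.05, "inferior")])
    def test_planted_block_recovered_with_reciprocal_overlap(self, block_freq, direction):
        params = HmmParams()
        block = (200_000, 240_000)
        for seed in range(20):
            counts = self._planted_counts(seed, block_freq)
            regions = call_regions(hmm_posteriors(counts, params), counts, params)
            assert len(regions) == 1
            (r,) = regions
            assert r.direction == direction
            inter = min(r.end, block[1]) - max(r.start, block[0]) + 1
            assert inter / max(r.length, block[1] - block[0] + 1) >= 0.5

    def test_specificity_under_neutral_model(self):
        # large-pool neutral genome: expected false calls per genome <= 0.5
        params = HmmParams()
        calls = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            m = 5_000
            chrom = np.repeat(np.arange(1, 11), m // 10)
            pos = np.concatenate([np.sort(rng.choice(750_000, m // 10, replace=False)) + 1
                                  for _ in range(10)])
            n = rng.poisson(100, m)
            k = rng.binomial(n, 0.5)
            counts = _counts(k, n, pos, chrom=chrom)
            calls.append(len(call_regions(hmm_posteriors(counts, params), counts, params)))
        assert np.mean(calls) <= 0.5

    def test_detection_monotone_in_effect_depth_and_pool_size(self):
        """Recovery rate of a planted block is non-decreasing along a
        3-point grid in block frequency, depth, and pool size."""
        params = HmmParams()
        block = (200_000, 240_000)

        def rate(block_freq=0.9, depth=100, pool_size=None, reps=30):
            hits = 0
            for seed in range(reps):
                rng = np.random.default_rng(seed)
                f = block_freq
                if pool_size is not None:   # finite pool: binomial composition
                    f = rng.binomial(pool_size, block_freq) / pool_size
                counts = self._planted_counts(seed, f, depth=depth)
                regions = call_regions(hmm_posteriors(counts, params), counts, params)
                hits += any(r.direction == "superior"
                            and min(r.end, block[1]) >= max(r.start, block[0])
                            for r in regions)
            return hits / reps

        effect = [rate(block_freq=f) for f in (0.6, 0.78, 0.95)]
        assert effect == sorted(effect)
        depth = [rate(block_freq=0.8, depth=d) for d in (15, 50, 150)]
        assert depth == sorted(depth)
        pool = [rate(block_freq=0.85, pool_size=s) for s in (8, 22, 200)]
        assert pool == sorted(pool)
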