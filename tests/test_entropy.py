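from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroentropy import (
    EntropyParams,
    SCALE_BINS,
    assign_scale_bin,
    check_length_adequacy,
    coarse_grain,
    cross_sample_entropy,
    mse_profile,
    sample_entropy,
    xmse_profile,
)

from _oracles import sampen_counts_oracle, sampen_oracle, xsampen_oracle


class TestCoarseGrain:
    def test_block_average_example(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5, 6], 2), [1.5, 3.5, 5.5])

    def test_tau_one_identity(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_scale20_length(self):
        assert coarse_grain(np.zeros(30_000), 20).size == 1500

    def test_tau_exceeding_length_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            coarse_grain(np.zeros(5), 6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        tau=st.integers(1, 8),
        blocks=st.integers(1, 20),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_grand_mean_preserved_when_tau_divides_n(self, tau, blocks, seed):
        x = np.random.default_rng(seed).normal(size=tau * blocks)
        assert coarse_grain(x, tau).mean() == pytest.approx(x.mean(), abs=1e-12)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.ones(50), 2, 0.1) == 0.0

    def test_periodic_series_matches_enumeration_oracle(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], dtype=float)
        a, b = sampen_counts_oracle(x, 2, 0.5)
        assert sample_entropy(x, 2, 0.5) == pytest.approx(-np.log(a / b), abs=1e-14)

    def test_matches_oracle_on_gaussian_noise(self, rng):
        x = rng.standard_normal(2000)
        r = 0.2 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(sampen_oracle(x, 2, r), abs=1e-10)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="short"):
            sample_entropy(np.arange(3.0), 2, 0.1)

    def test_zero_tolerance_raises(self):
        with pytest.raises(ValueError, match="tolerance"):
            sample_entropy(np.arange(50.0), 2, 0.0)

    def test_scale_invariance_with_relative_tolerance(self, rng):
        x = rng.standard_normal(500)
        e1 = sample_entropy(x, 2, 0.2 * x.std())
        for c in (0.01, 3.0, 1e4):
            assert sample_entropy(c * x, 2, 0.2 * (c * x).std()) == pytest.approx(
                e1, abs=1e-12
            )

    def test_monotone_nonincreasing_in_r(self, rng):
        x = rng.standard_normal(400)
        rs = np.array([0.1, 0.2, 0.4, 0.8]) * x.std()
        es = [sample_entropy(x, 2, r) for r in rs]
        assert all(a >= b - 1e-12 for a, b in zip(es, es[1:]))

    def test_undefined_returns_nan(self):
        # strictly increasing with huge steps: no m+1 template matches
        x = np.array([0.0, 10.0, 0.5, 30.0, 1.0, 50.0, 1.5, 70.0])
        assert np.isnan(sample_entropy(x, 2, 0.6))

    def test_base2_is_natural_over_log2(self, rng):
        x = rng.standard_normal(300)
        r = 0.2 * x.std()
        nat = sample_entropy(x, 2, r)
        bits = sample_entropy(x, 2, r, log_base="2")
        assert bits == pytest.approx(nat / np.log(2), rel=1e-12)


class TestCrossSampleEntropy:
    def test_symmetry(self, rng):
        u, v = rng.standard_normal((2, 300))
        assert cross_sample_entropy(u, v, 2, 0.3) == pytest.approx(
            cross_sample_entropy(v, u, 2, 0.3), abs=1e-14
        )

    def test_identical_constant_series_zero(self):
        assert cross_sample_entropy(np.ones(30), np.ones(30), 2, 0.1) == 0.0

    def test_short_pair_matches_enumeration_oracle(self):
        u = np.array([0.0, 1.0, 0.2, 0.8, 0.4, 0.6, 0.1])
        v = np.array([0.1, 0.9, 0.3, 0.7, 0.5, 0.4, 0.2])
        assert cross_sample_entropy(u, v, 1, 0.25) == pytest.approx(
            xsampen_oracle(u, v, 1, 0.25), abs=1e-14
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_sample_entropy(np.zeros(10), np.zeros(11), 2, 0.1)


class TestLengthAdequacy:
    @pytest.mark.parametrize(
        "n,m,status",
        [(1500, 2, "pass"), (99, 2, "fail"), (250, 2, "warn"), (400, 2, "pass"),
         (10, 1, "warn"), (9, 1, "fail"), (20, 1, "pass")],
    )
    def test_thresholds(self, n, m, status):
        assert check_length_adequacy(n, m)[0] == status


class TestScaleBins:
    @pytest.mark.parametrize(
        "scale,label",
        [(1, "fine"), (5, "fine"), (6, "medium"), (10, "medium"),
         (11, "coarse"), (15, "coarse"), (16, "very-coarse"), (20, "very-coarse")],
    )
    def test_bin_assignment(self, scale, label):
        assert assign_scale_bin(scale) == label

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            assign_scale_bin(21)

    def test_bins_partition_1_to_20(self):
        all_scales = sorted(s for scales in SCALE_BINS.values() for s in scales)
        assert all_scales == list(range(1, 21))


class TestMSEProfile:
    def test_sinusoid_low_entropy_at_every_scale(self):
        t = np.arange(30_000) / 1000.0
        x = np.sin(2 * np.pi * 5.0 * t)
        prof = mse_profile(x, EntropyParams())
        # ~2.2 nats for broadband noise; "near zero" for a clean oscillation
        assert np.all(prof.entropy_by_scale < 0.4)

    def test_white_noise_declines_with_scale(self, rng):
        x = rng.standard_normal(10_000)
        prof = mse_profile(x, EntropyParams())
        e = prof.entropy_by_scale
        assert e[0] > e[-1]

    def test_shuffled_surrogates_raise_coarse_entropy_of_correlated_input(self, rng):
        # strong autocorrelation concentrates variance at slow timescales;
        # shuffling destroys it, so coarse-grained surrogates look whiter
        # but with far less variance removed by averaging → higher SampEn
        x = np.cumsum(rng.standard_normal(4000))
        x = (x - x.mean()) / x.std()
        r = 0.2
        orig = sample_entropy(coarse_grain(x, 10), 2, r)
        surr = []
        for _ in range(20):
            s = rng.permutation(x)
            surr.append(sample_entropy(coarse_grain(s, 10), 2, r))
        assert np.mean(surr) > orig

    def test_strict_length_check(self):
        with pytest.raises(ValueError, match="floor"):
            mse_profile(np.random.default_rng(0).normal(size=900),
                        EntropyParams(max_scale=20), strict_length=True)

    def test_r_per_scale_policy_differs_from_fixed(self, rng):
        x = np.cumsum(rng.standard_normal(4000))
        fixed = mse_profile(x, EntropyParams(r_policy="fixed"))
        per = mse_profile(x, EntropyParams(r_policy="per-scale"))
        assert not np.allclose(fixed.entropy_by_scale, per.entropy_by_scale)


class TestXMSEProfile:
    def test_profile_length_and_self_pair(self, rng):
        u = rng.standard_normal(3000)
        params = EntropyParams(max_scale=10)
        self_prof = xmse_profile(u, u.copy(), params)
        assert self_prof.cross_entropy_by_scale.size == 10
        noise_prof = xmse_profile(u, rng.standard_normal(3000), params)
        # matching a series against itself is easier than against an
        # independent one at the finest scale
        assert self_prof.cross_entropy_by_scale[0] < noise_prof.cross_entropy_by_scale[0]

    def test_shared_source_lowers_cross_entropy(self, rng):
        src = rng.standard_normal(3000)
        a = src + 0.1 * rng.standard_normal(3000)
        b = src + 0.1 * rng.standard_normal(3000)
        ind1, ind2 = rng.standard_normal((2, 3000))
        params = EntropyParams(max_scale=5)
        corr = xmse_profile(a, b, params).cross_entropy_by_scale[0]
        indep = xmse_profile(ind1, ind2, params).cross_entropy_by_scale[0]
        assert corr < indep
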