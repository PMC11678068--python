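import numpy as np
import pytest
from hypothesis import given, strategies as st

import divergelens as dl


class TestRankNearestSmooth:
    def test_full_neighborhood_gives_global_mean(self):
        out = dl.rank_nearest_smooth([1.0, 2.0, 3.0], [10.0, 20.0, 30.0], m=3)
        assert out == pytest.approx([2.0, 2.0, 2.0])

    def test_single_neighbor_is_identity_for_distinct_z(self):
        x = [5.0, 6.0, 7.0]
        out = dl.rank_nearest_smooth(x, [1.0, 2.0, 3.0], m=1)
        assert out == pytest.approx(x)

    def test_neighborhood_selection(self):
        out = dl.rank_nearest_smooth([1.0, 2.0, 3.0, 10.0], [1.0, 2.0, 3.0, 10.0], m=3)
        assert out[0] == pytest.approx(np.mean([1, 2, 3]))
        assert out[3] == pytest.approx(np.mean([10, 3, 2]))

    def test_distance_ties_prefer_smaller_index(self):
        # z = (0, 1, 2): for the middle point both neighbours are at
        # distance 1; the smaller index wins
        out = dl.rank_nearest_smooth([10.0, 0.0, 30.0], [0.0, 1.0, 2.0], m=2)
        assert out[1] == pytest.approx((10.0 + 0.0) / 2)

    def test_m_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            dl.rank_nearest_smooth([1.0, 2.0], [1.0, 2.0], m=3)

    @given(st.permutations(list(range(8))))
    def test_permutation_equivariance(self, perm):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        z = rng.normal(size=8)
        perm = np.asarray(perm)
        base = dl.rank_nearest_smooth(x, z, m=3)
        permuted = dl.rank_nearest_smooth(x[perm], z[perm], m=3)
        # identical z-neighbourhoods up to reindexing when z values distinct
        assert permuted == pytest.approx(base[perm])


class TestSimulateXyz:
    def test_zero_noise_collapses_to_z(self):
        x, y, z = dl.simulate_xyz(100, 0.0, seed=0)
        assert x == pytest.approx(z)
        assert y == pytest.approx(z)

    def test_reproducible_under_seed(self):
        a = dl.simulate_xyz(50, 1.0, seed=9)
        b = dl.simulate_xyz(50, 1.0, seed=9)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)

    def test_marginal_correlation_matches_closed_form(self):
        """For identity links, population cor(x, y) = 1/(1 + noise_sd²)."""
        noise_sd = 2.0
        x, y, z = dl.simulate_xyz(20_000, noise_sd, seed=4)
        rho = 1.0 / (1.0 + noise_sd**2)
        se = (1 - rho**2) / np.sqrt(20_000)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(rho, abs=3 * se)


class TestCorrelationMatrices:
    def test_identical_vectors_give_all_ones(self):
        v = np.arange(200.0)
        old, new = dl.correlation_matrices(v, v, v, m=10)
        assert old == pytest.approx(np.ones((3, 3)))
        assert new == pytest.approx(np.ones((3, 3)))

    def test_independent_noise_stays_uncorrelated(self):
        rng = np.random.default_rng(8)
        x, y, z = rng.normal(size=(3, 10_000))
        old, _ = dl.correlation_matrices(x, y, z, m=100)
        off = old[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_smoothing_recovers_shared_dependence(self):
        """Noise buries the marginal x–y correlation; conditional-expectation
        smoothing over z recovers it."""
        x, y, z = dl.simulate_xyz(5000, 3.0, seed=0)
        old, new = dl.correlation_matrices(x, y, z, m=100)
        assert abs(old[0, 1]) < 0.3
        assert new[0, 1] > 0.8

    def test_zero_variance_flagged_as_nan(self):
        old, _ = dl.correlation_matrices(
            np.ones(50), np.arange(50.0), np.arange(50.0), m=5
        )
        assert np.isnan(old[0, 1])
        assert old[1, 2] == pytest.approx(1.0)


class TestPermCorrDiffTest:
    def test_worked_example_exhaustive(self):
        res = dl.perm_corr_diff_test([1, 2, 3], [3, 2, 1], [1, 2, 3])
        assert res.diff == pytest.approx(2.0)
        assert res.p == pytest.approx(0.25)
        assert res.exhaustive and res.n_perm == 8

    def test_equal_vectors_give_p_one(self):
        x = [1.0, 4.0, 2.0, 8.0]
        res = dl.perm_corr_diff_test(x, x, [1.0, 2.0, 3.0, 4.0])
        assert res.diff == 0.0
        assert res.p == 1.0

    def test_exhaustive_p_is_dyadic(self):
        rng = np.random.default_rng(1)
        res = dl.perm_corr_diff_test(
            rng.normal(size=8), rng.normal(size=8), rng.normal(size=8)
        )
        assert res.exhaustive
        assert (res.p * 2**8) == pytest.approx(round(res.p * 2**8))

    def test_exhaustive_distribution_is_antisymmetric(self):
        """Complementary swap patterns negate the statistic, so the
        exhaustive aligned-mode distribution has mean zero."""
        rng = np.random.default_rng(2)
        x, y, z = rng.normal(size=(3, 10))
        from divergelens.correlations import _row_corr_with

        n = 10
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        S = bits.astype(bool)
        d = _row_corr_with(np.where(S, x, y), z) - _row_corr_with(np.where(S, y, x), z)
        assert d.mean() == pytest.approx(0.0, abs=1e-12)
        assert d == pytest.approx(-d[::-1])

    def test_sampling_mode_kicks_in_above_cap(self):
        rng = np.random.default_rng(3)
        res = dl.perm_corr_diff_test(
            rng.normal(size=20), rng.normal(size=20), rng.normal(size=20), cap=2000, seed=5
        )
        assert not res.exhaustive
        assert res.n_perm == 2000

    def test_literal_mode_matches_aligned_on_prefix_patterns(self):
        """For all-true and all-false swap patterns the concatenation
        construction coincides with the aligned one, so the observed diff is
        identical; p-values may differ."""
        rng = np.random.default_rng(4)
        x, y, z = rng.normal(size=(3, 6))
        a = dl.perm_corr_diff_test(x, y, z, mode="aligned")
        l = dl.perm_corr_diff_test(x, y, z, mode="literal")
        assert a.diff == pytest.approx(l.diff)
        assert 0 <= l.p <= 1

    def test_type_one_error_with_fixed_direction(self):
        """Exhaustive test on exchangeable nulls is calibrated when the tail
        is fixed a priori; the sign-adaptive rule roughly doubles the rate."""
        rng = np.random.default_rng(7)
        rej_fixed = rej_auto = 0
        n_rep = 400
        for _ in range(n_rep):
            z = rng.standard_normal(12)
            x = z + rng.normal(0, 1, 12)
            y = z + rng.normal(0, 1, 12)
            res = dl.perm_corr_diff_test(x, y, z, alternative="greater")
            rej_fixed += res.p <= 0.05
            rej_auto += dl.perm_corr_diff_test(x, y, z).p < 0.05
        assert 0.03 <= rej_fixed / n_rep <= 0.07
        assert rej_auto / n_rep > rej_fixed / n_rep

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            dl.perm_corr_diff_test([1, 2], [2, 1], [1, 2])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dl.perm_corr_diff_test([1, 1, 1], [1, 2, 3], [1, 2, 3])
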