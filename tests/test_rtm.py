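"""Change index, surrogate engine (vs exhaustive oracle), DI and tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnorate import (
    cell_change_index,
    change_index,
    deflection_index,
    delta_log_fr,
    group_change_index,
    report_tests,
    shuffle_surrogates,
)

from oracles import exhaustive_flip_surrogates

rate_vectors = st.lists(
    st.floats(0.0, 50.0, allow_nan=False), min_size=5, max_size=30
).map(np.asarray)


class TestChangeIndex:
    @pytest.mark.parametrize(
        "fi,fj,expect",
        [(1.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.9, 1.1, -0.1), (0.0, 2.0, -1.0)],
    )
    def test_cell_examples(self, fi, fj, expect):
        assert cell_change_index(np.array([fi]), np.array([fj]))[0] == pytest.approx(expect)

    def test_both_silent_is_nan_and_excluded(self):
        ci = cell_change_index(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isnan(ci[0]) and ci[1] == 0.0
        res = change_index(np.array([0.0, 1, 2, 3, 4, 5]), np.array([0.0, 1, 2, 3, 4, 5]))
        assert res.n_excluded == 1

    def test_all_silent_errors(self):
        with pytest.raises(ValueError):
            change_index(np.zeros(5), np.zeros(5))

    def test_group_ci_is_ci_of_means(self):
        fi = np.array([1.0, 3.0])
        fj = np.array([2.0, 2.0])
        # means: 2.0 vs 2.0 -> 0, even though per-cell CIs are -1/3 and +1/5
        assert group_change_index(fi, fj) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=100)
    @given(fi=rate_vectors, fj=rate_vectors)
    def test_antisymmetry_and_bounds(self, fi, fj):
        n = min(fi.size, fj.size)
        fi, fj = fi[:n], fj[:n]
        a = cell_change_index(fi, fj)
        b = cell_change_index(fj, fi)
        ok = ~np.isnan(a)
        np.testing.assert_allclose(a[ok], -b[ok], atol=1e-12)
        assert np.all(np.abs(a[ok]) <= 1.0 + 1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(fi=rate_vectors, fj=rate_vectors, c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, fi, fj, c):
        n = min(fi.size, fj.size)
        fi, fj = fi[:n], fj[:n]
        a = cell_change_index(fi, fj)
        b = cell_change_index(c * fi, c * fj)
        ok = ~np.isnan(a)
        np.testing.assert_allclose(a[ok], b[ok], atol=1e-9)


class TestDeltaLog:
    def test_examples(self):
        d, n_exc = delta_log_fr(np.array([1.0, 1.0]), np.array([1.0, 10.0]))
        np.testing.assert_allclose(d, [0.0, 1.0])
        assert n_exc == 0

    def test_zero_rates_excluded(self):
        d, n_exc = delta_log_fr(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert np.isnan(d).all() and n_exc == 2

    def test_sign_opposite_to_ci(self):
        rng = np.random.default_rng(0)
        fi = rng.uniform(0.1, 10, 200)
        fj = rng.uniform(0.1, 10, 200)
        ci = cell_change_index(fi, fj)
        d, _ = delta_log_fr(fi, fj)
        assert np.all(np.sign(d) == -np.sign(ci))


class TestSurrogates:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        fi, fk = rng.uniform(0, 5, 20), rng.uniform(0, 5, 20)
        a = shuffle_surrogates(fi, fk, n_shuffles=100, seed=9)
        b = shuffle_surrogates(fi, fk, n_shuffles=100, seed=9)
        for g in a.values:
            np.testing.assert_array_equal(a.values[g], b.values[g])

    def test_identical_i_and_k_gives_all_zero_surrogates(self):
        """With FR_i = FR_k every flipped pair is identical, so every
        surrogate within-state CI is exactly zero and DI equals observed CI."""
        fi = np.linspace(0.5, 5.0, 10)
        surr = shuffle_surrogates(fi, fi.copy(), n_shuffles=50, seed=0)
        for g, vals in surr.values.items():
            np.testing.assert_allclose(vals, 0.0, atol=1e-12)
        fj = fi * 1.5
        res = change_index(fi, fj)
        di = deflection_index(res, surr)
        for g, gdi in di.groups.items():
            assert gdi.di == pytest.approx(gdi.observed_ci, abs=1e-12)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """For 8 cells the 2^8 flip patterns are enumerable exactly; the
        seeded Monte-Carlo mean must sit within 3 MC standard errors."""
        rng = np.random.default_rng(2)
        fi = rng.lognormal(0, 1, 8)
        fk = rng.lognormal(0, 1, 8)
        exact = exhaustive_flip_surrogates(fi, fk, n_groups=4)
        mc = shuffle_surrogates(fi, fk, n_shuffles=2000, seed=3, n_groups=4)
        for g, exact_vals in exact.items():
            se = exact_vals.std(ddof=0) / np.sqrt(2000)
            assert np.mean(mc.values[g]) == pytest.approx(exact_vals.mean(), abs=3 * se + 1e-12)

    def test_band_brackets_surrogate_mean(self):
        rng = np.random.default_rng(4)
        fi, fk = rng.lognormal(0, 1, 30), rng.lognormal(0, 1, 30)
        surr = shuffle_surrogates(fi, fk, n_shuffles=500, seed=5)
        for g in surr.values:
            lo, hi = surr.band(g)
            assert lo <= surr.mean(g) <= hi


class TestDeflection:
    def test_di_arithmetic_and_p(self):
        surr = shuffle_surrogates(
            np.linspace(0.5, 5, 10), np.linspace(5, 0.5, 10), n_shuffles=400, seed=6
        )
        obs = {g: 0.2 for g in surr.values}
        di = deflection_index(obs, surr)
        for g, gdi in di.groups.items():
            assert gdi.di == pytest.approx(0.2 - gdi.surrogate_mean, abs=1e-12)
            assert gdi.band_lo <= gdi.surrogate_mean <= gdi.band_hi
            assert 0.0 < gdi.p_empirical <= 1.0


class TestReportTests:
    def test_signed_rank_all_zero_differences(self):
        res = report_tests("paired_signed_rank", np.zeros(30))
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_ks_identical_samples(self):
        x = np.linspace(0, 1, 50)
        res = report_tests("ks_2sample", x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_small_n_flagged(self):
        res = report_tests("paired_signed_rank", np.array([0.1, 0.2]))
        assert res.flagged and np.isnan(res.p_value)

    def test_anova_null_calibration(self):
        """Type-I error of the one-way ANOVA near 0.05 under the null."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 20) for _ in range(5)]
            if report_tests("anova", *groups).p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07  # 3 sigma of binomial(1000, 0.05)

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            report_tests("bootstrap", np.ones(3))
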