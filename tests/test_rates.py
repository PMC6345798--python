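"""Rate computation, quintile assignment, traces and CV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnorate import (
    CellClass,
    IntervalSet,
    SpikeTable,
    UnitRecord,
    assign_quintiles,
    count_spikes_in,
    period_rates,
    population_cv,
    quintile_traces,
    sliding_rates,
    time_normalized_rates,
)
from somnorate.rates import quintile_of_rank

from oracles import brute_force_count


def one_unit(times):
    return SpikeTable([UnitRecord("u0", "hpc", CellClass.PRINCIPAL, np.asarray(times, float))])


class TestCounting:
    def test_example(self):
        count, dur = count_spikes_in(one_unit([1.0, 2.0, 3.0]).units[0], IntervalSet([(0, 2.5)]))
        assert (count, dur) == (2, 2.5)

    def test_half_open_end_not_counted(self):
        count, _ = count_spikes_in(one_unit([2.0]).units[0], IntervalSet([(0, 2.0)]))
        assert count == 0

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0, 100, 10_000))
        edges = np.sort(rng.uniform(0, 100, 8))
        mask = IntervalSet([(edges[0], edges[3]), (edges[4], edges[7])])
        count, dur = count_spikes_in(one_unit(spikes).units[0], mask)
        assert count == brute_force_count(spikes, list(mask))
        # rate over the mask approximates the global rate
        assert count / dur == pytest.approx(100.0, rel=0.1)


class TestSlidingRates:
    def test_regular_train_flat(self):
        table = one_unit(np.arange(0, 300, 0.1))
        m = sliding_rates(table, (0.0, 300.0))
        assert np.all(np.abs(m.rates - 10.0) < 0.2)

    def test_silent_unit_zero(self):
        m = sliding_rates(one_unit([]), (0.0, 300.0))
        assert np.all(m.rates == 0.0)

    def test_poisson_grand_mean(self):
        rng = np.random.default_rng(2)
        n = rng.poisson(5.0 * 600)
        table = one_unit(np.sort(rng.uniform(0, 600, n)))
        m = sliding_rates(table, (0.0, 600.0))
        se = np.sqrt(5.0 / 600.0)  # SE of the overall mean rate
        assert abs(np.mean(m.rates) - 5.0) < 3 * se + 0.1

    def test_empty_session_errors(self):
        with pytest.raises(ValueError):
            sliding_rates(one_unit([1.0]), (10.0, 10.0))

    def test_mask_consistency_with_manual_restriction(self):
        """Rates on NREM minus OFF equal counts/durations on the set difference."""
        rng = np.random.default_rng(3)
        table = one_unit(np.sort(rng.uniform(0, 120, 2000)))
        mask = IntervalSet([(10, 14), (40, 41), (90, 100)])
        m = sliding_rates(table, (0.0, 120.0), mask=mask)
        for b in range(m.n_bins):
            window = IntervalSet([(m.bin_starts[b], m.bin_ends[b])]).subtract(mask)
            count, dur = count_spikes_in(table.units[0], window)
            assert m.occupancy_s[b] == pytest.approx(dur, abs=1e-9)
            assert m.rates[0, b] == pytest.approx(count / dur)


class TestTimeNormalized:
    def test_thirty_bins_of_300s_nrem(self):
        m = time_normalized_rates(one_unit([]), (0.0, 300.0), 30)
        assert m.n_bins == 30
        np.testing.assert_allclose(m.bin_ends - m.bin_starts, 10.0)

    def test_single_spike_bin_rate(self):
        # 120 s epoch, 10 bins of 12 s; one spike in bin 7
        m = time_normalized_rates(one_unit([80.0]), (0.0, 120.0), 10)
        expect = np.zeros(10)
        expect[6] = 1.0 / 12.0
        np.testing.assert_allclose(m.rates[0], expect)

    def test_fully_masked_bin_missing_not_zero(self):
        mask = IntervalSet([(0.0, 12.0)])
        m = time_normalized_rates(one_unit([50.0]), (0.0, 120.0), 10, mask=mask)
        assert np.isnan(m.rates[0, 0])
        assert m.occupancy_s[0] == 0.0

    def test_poisson_per_bin_mean(self):
        rng = np.random.default_rng(4)
        rates = []
        for _ in range(200):
            n = rng.poisson(3.0 * 60)
            m = time_normalized_rates(one_unit(np.sort(rng.uniform(0, 60, n))), (0, 60), 10)
            rates.append(m.rates[0])
        grand = np.mean(rates)
        assert grand == pytest.approx(3.0, abs=3 * np.sqrt(3.0 / (200 * 60)))


class TestQuintiles:
    def test_ten_cells_two_per_quintile(self):
        a = assign_quintiles(np.arange(1.0, 11.0), [f"u{i:02d}" for i in range(10)])
        np.testing.assert_array_equal(a.quintile, [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])

    def test_seven_cell_sizes_from_ceil_rule(self):
        # ceil(5r/7) for r=1..7 gives groups 1,2,3,3,4,5,5
        np.testing.assert_array_equal(quintile_of_rank(np.arange(1, 8), 7), [1, 2, 3, 3, 4, 5, 5])
        a = assign_quintiles(np.arange(7.0), [f"u{i}" for i in range(7)])
        sizes = [int(np.sum(a.quintile == q)) for q in range(1, 6)]
        assert sizes == [1, 1, 2, 1, 2]

    def test_all_equal_rates_tie_break_by_unit_id(self):
        ids = ["c", "a", "b", "e", "d"]
        a = assign_quintiles(np.ones(5), ids)
        by_id = a.as_dict()
        assert [by_id[i] for i in sorted(ids)] == [1, 2, 3, 4, 5]

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError):
            assign_quintiles(np.arange(4.0), ["a", "b", "c", "d"])

    @settings(derandomize=True, max_examples=50)
    @given(rates=st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=40))
    def test_invariant_under_monotone_transform(self, rates):
        rates = np.asarray(rates)
        ids = [f"u{i:03d}" for i in range(rates.size)]
        base = assign_quintiles(rates, ids)
        # scaling by a power of two is exactly monotone and injective in floats
        transformed = assign_quintiles(rates * 4.0, ids)
        np.testing.assert_array_equal(base.quintile, transformed.quintile)

    def test_partition_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(5)
        for n in (5, 6, 7, 11, 23, 100, 101):
            a = assign_quintiles(rng.uniform(0, 5, n), [f"u{i:03d}" for i in range(n)])
            sizes = np.bincount(a.quintile, minlength=6)[1:]
            assert sizes.sum() == n
            assert sizes.max() - sizes.min() <= 1


class TestQuintileTraces:
    def _matrix(self, rates):
        from somnorate.rates import RateMatrix

        n_bins = rates.shape[1]
        starts = 10.0 * np.arange(n_bins)
        return RateMatrix(
            cell_ids=np.array([f"u{i:02d}" for i in range(rates.shape[0])]),
            bin_starts=starts,
            bin_ends=starts + 10.0,
            rates=rates,
            occupancy_s=np.full(n_bins, 10.0),
        )

    def test_constant_population_normalizes_to_one(self):
        rates = np.tile(np.arange(1.0, 11.0)[:, None], (1, 6))
        m = self._matrix(rates)
        a = assign_quintiles(rates[:, 0], m.cell_ids)
        tr = quintile_traces(m, a, reference_period=(0.0, 30.0))
        np.testing.assert_allclose(tr.normalized, 1.0)

    def test_scale_equivariance_after_reference(self):
        rates = np.tile(np.arange(1.0, 11.0)[:, None], (1, 6))
        rates[:, 3:] *= 2.0
        m = self._matrix(rates)
        a = assign_quintiles(rates[:, 0], m.cell_ids)
        tr = quintile_traces(m, a, reference_period=(0.0, 30.0))
        np.testing.assert_allclose(tr.normalized[:, 3:], 2.0)
        np.testing.assert_allclose(tr.normalized[:, :3], 1.0)

    def test_reference_mean_exactly_one(self):
        rng = np.random.default_rng(6)
        rates = rng.uniform(0.5, 5.0, size=(15, 8))
        m = self._matrix(rates)
        a = assign_quintiles(rates[:, 0], m.cell_ids)
        tr = quintile_traces(m, a, reference_period=(0.0, 40.0))
        ref = tr.normalized[:, :4].mean(axis=1)
        np.testing.assert_allclose(ref, 1.0, atol=1e-9)

    def test_zero_reference_flagged_not_divided(self):
        rates = np.zeros((5, 4))
        rates[:, 2:] = 1.0
        m = self._matrix(rates)
        a = assign_quintiles(rates[:, 0], m.cell_ids)
        tr = quintile_traces(m, a, reference_period=(0.0, 20.0))
        assert tr.flagged.all()
        assert np.all(np.isnan(tr.normalized))

    def test_planted_rem_widening_orders_traces(self):
        """Quintile-dependent gains after the reference separate in order."""
        rng = np.random.default_rng(7)
        base = np.sort(rng.lognormal(0, 1, 25))
        gains = np.repeat([0.6, 0.8, 0.9, 1.0, 1.1], 5)
        rates = np.tile(base[:, None], (1, 10)).astype(float)
        rates[:, 5:] *= gains[:, None]
        m = self._matrix(rates)
        a = assign_quintiles(rates[:, 0], m.cell_ids)
        tr = quintile_traces(m, a, reference_period=(0.0, 50.0))
        late = tr.normalized[:, 5:].mean(axis=1)
        assert np.all(np.diff(late) > 0)  # planted order recovered


class TestPopulationCV:
    def test_constant_rates_zero(self):
        assert population_cv(np.ones(4)).cv == 0.0

    def test_two_point_example(self):
        assert population_cv(np.array([0.5, 1.5])).cv == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        r = rng.uniform(0.1, 5, 50)
        assert population_cv(3.7 * r).cv == pytest.approx(population_cv(r).cv, rel=1e-12)

    def test_lognormal_closed_form(self):
        sigma = 0.8
        rng = np.random.default_rng(9)
        r = rng.lognormal(0.0, sigma, 200_000)
        expect = np.sqrt(np.exp(sigma**2) - 1.0)
        assert population_cv(r).cv == pytest.approx(expect, rel=0.02)

    def test_zero_mean_flagged(self):
        res = population_cv(np.zeros(5))
        assert res.undefined and np.isnan(res.cv)

    def test_period_rates_mask_lowers_duration_not_counts_outside(self, regular_spikes):
        rates, dur = period_rates(regular_spikes, (0.0, 100.0))
        masked, mdur = period_rates(regular_spikes, (0.0, 100.0), mask=IntervalSet([(50, 60)]))
        assert mdur == pytest.approx(90.0)
        assert dur == pytest.approx(100.0)
        # regular trains: masked rate stays near the nominal rate
        np.testing.assert_allclose(masked[:-1], rates[:-1], rtol=0.05)
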