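import numpy as np
import pytest
from scipy.stats import spearmanr

from popwave import (
    PopulationPETH,
    TimeGrid,
    WaveConfig,
    average_across_conditions,
    build_peak_table,
    gaussian_bump,
    normalize_for_display,
    order_by_peak,
    pairwise_correlation,
    simulate_wave,
    split_subpopulations,
)
from popwave.experiments import ordering_wave


class TestAverageAcrossConditions:
    def test_identical_conditions_average_to_one_condition(self, small_wave):
        rates = np.repeat(small_wave.rates[:, :1], 4, axis=1)
        pop = PopulationPETH(rates, small_wave.grid)
        np.testing.assert_allclose(average_across_conditions(pop), rates[:, 0])

    def test_arithmetic_mean_of_scaled_conditions(self, small_grid):
        r = np.random.default_rng(0).random((3, 1, small_grid.n_samples))
        pop = PopulationPETH(np.concatenate([r, 3 * r], axis=1), small_grid)
        np.testing.assert_allclose(average_across_conditions(pop), 2 * r[:, 0])

    def test_wave_average_peaks_at_tau(self, small_wave):
        avg = average_across_conditions(small_wave)
        peaks = small_wave.grid.times[np.argmax(avg, axis=1)]
        np.testing.assert_allclose(peaks, 10.0 * np.arange(12))


class TestOrderByPeak:
    def test_sorted_input_gives_identity(self, small_wave):
        avg = average_across_conditions(small_wave)
        table = order_by_peak(avg, small_wave.grid)
        np.testing.assert_array_equal(table.order, np.arange(12))

    def test_reversed_input_gives_reversal(self, small_wave):
        avg = average_across_conditions(small_wave)[::-1]
        table = order_by_peak(avg, small_wave.grid)
        np.testing.assert_array_equal(table.order, np.arange(12)[::-1])

    def test_idempotent_on_ordered_data(self, small_wave):
        avg = average_across_conditions(small_wave)
        first = order_by_peak(avg, small_wave.grid)
        again = order_by_peak(avg[first.order], small_wave.grid)
        np.testing.assert_array_equal(again.order, np.arange(12))

    def test_constant_row_flagged_degenerate(self, small_grid):
        avg = np.vstack([np.ones(small_grid.n_samples), gaussian_bump(small_grid, 50.0, 1.0)])
        table = order_by_peak(avg, small_grid)
        assert table.degenerate[0] and not table.degenerate[1]
        assert table.peak_ms[0] == small_grid.start

    def test_ten_ms_lag_wave_recovers_identity(self):
        pop = simulate_wave(ordering_wave(seed=4))
        table = build_peak_table(pop)
        np.testing.assert_array_equal(table.order, np.arange(pop.n_neurons))

    def test_condition_scatter_rank_correlates_with_true_sequence(self):
        # one grid bin of lag per neuron: the per-condition peak scatter
        # recovers the true neuron ordering almost perfectly
        pop = simulate_wave(ordering_wave(seed=4))
        table = build_peak_table(pop)
        true_tau = ordering_wave(seed=4).peak_times()
        rho = spearmanr(table.condition_peak_ms.ravel(), true_tau.ravel()).statistic
        assert rho >= 0.99


class TestSplitSubpopulations:
    @pytest.mark.parametrize(
        "n_neurons,n_groups,expected",
        [(218, 3, (73, 73, 72)), (6, 3, (2, 2, 2)), (7, 3, (3, 2, 2))],
    )
    def test_ceil_first_group_sizes(self, n_neurons, n_groups, expected, small_grid):
        rng = np.random.default_rng(0)
        pop = PopulationPETH(rng.random((n_neurons, 2, small_grid.n_samples)), small_grid)
        table = order_by_peak(average_across_conditions(pop), small_grid)
        split = split_subpopulations(table, n_groups)
        assert split.sizes == expected
        assert len(split.group_of_neuron) == n_neurons

    def test_group_average_of_identical_neurons_is_exact(self, small_grid):
        bump = gaussian_bump(small_grid, 50.0, 1.0)
        pop = PopulationPETH(np.tile(bump, (4, 2, 1)), small_grid)
        table = order_by_peak(average_across_conditions(pop), small_grid)
        split = split_subpopulations(table, 2, pop)
        np.testing.assert_allclose(split.group_condition_avg, np.tile(bump, (2, 2, 1)))

    def test_too_many_groups_rejected(self, small_wave):
        table = order_by_peak(average_across_conditions(small_wave), small_wave.grid)
        with pytest.raises(ValueError):
            split_subpopulations(table, 13)


class TestPairwiseCorrelation:
    def test_self_and_negation(self):
        x = gaussian_bump(TimeGrid(0, 100, 10), 50.0, 1.0)
        corr = pairwise_correlation(np.vstack([x, -x]))
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_correlation_decreases_with_peak_offset(self):
        # brute force over an offset grid: wider kernel keeps overlap alive
        grid = TimeGrid(0.0, 600.0, 10.0)
        offsets = np.arange(0, 201, 20.0)
        rows = np.vstack([gaussian_bump(grid, 200.0 + d, 1.0, width_param=5000.0) for d in offsets])
        corr = pairwise_correlation(rows)[0]
        assert np.all(np.diff(corr) < 0)

    def test_positive_semidefinite(self, small_wave):
        corr = pairwise_correlation(average_across_conditions(small_wave))
        assert np.linalg.eigvalsh(corr).min() >= -1e-10

    def test_zero_variance_row_yields_nan_with_warning(self, small_grid):
        rows = np.vstack([np.ones(small_grid.n_samples), gaussian_bump(small_grid, 50.0, 1.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = pairwise_correlation(rows)
        assert np.isnan(corr[0]).all() and corr[1, 1] == 1.0


class TestNormalizeForDisplay:
    def test_constant_vector_maps_to_zero(self):
        np.testing.assert_array_equal(normalize_for_display(np.full(5, 3.0)), np.zeros(5))

    def test_new_maximum_is_peak_minus_mean_over_peak(self):
        x = np.array([0.0, 1.0, 4.0, 1.0])
        out = normalize_for_display(x)
        assert out.max() == pytest.approx((4.0 - 1.5) / 4.0)

    def test_scale_invariance(self):
        x = np.array([0.1, 0.5, 2.0, 0.3])
        np.testing.assert_allclose(normalize_for_display(7.3 * x), normalize_for_display(x))

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            normalize_for_display(np.zeros(4))
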