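"""Task resampling, bootstrap ensembles and uncertainty bands."""

import numpy as np
import pytest

from tdsboot import (
    BootstrapEnsemble,
    TaskRecord,
    TDSValidationError,
    TimeGrid,
    band_from_order_statistics,
    bootstrap_curves,
    compute_curves,
    normal_bands,
    percentile_rank,
    resample_tasks,
    simulate_population,
    simulate_state_matrix,
    curves_from_states,
    ensemble_from_states,
    exact_marginals,
)

from _helpers import kth_smallest_by_counting, random_tasks


def make_ensemble(values_qpg, base=None, m=100):
    values_qpg = np.asarray(values_qpg, dtype=float)
    _, p, g = values_qpg.shape
    grid = TimeGrid.uniform(g)
    descriptors = tuple(f"D{j+1}" for j in range(p))
    if base is None:
        base = curves_from_states(np.zeros((1, g), dtype=int), descriptors, grid)
    return BootstrapEnsemble(base, values_qpg, m=m)


class TestResampleTasks:
    def test_single_task_resamples_to_itself(self):
        t = TaskRecord("only", 0.0, 1.0, (("A", 0.0),))
        assert resample_tasks([t], np.random.default_rng(0)) == [t]

    def test_empty_input_errors(self):
        with pytest.raises(TDSValidationError, match="empty"):
            resample_tasks([], np.random.default_rng(0))

    def test_absence_probability_approaches_inv_e(self, rng):
        m, reps = 50, 2000
        tasks = random_tasks(m, rng)
        absent = sum(tasks[0] not in resample_tasks(tasks, rng) for _ in range(reps))
        expected = (1 - 1 / m) ** m  # -> 1/e for large m
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(absent / reps - expected) < 4 * se


class TestBootstrapCurves:
    def test_replicates_match_literal_resampling(self, case1):
        tasks = simulate_population(case1, 30, np.random.default_rng(5))
        ens = bootstrap_curves(
            tasks, case1.descriptors, case1.grid, q=5, rng=np.random.default_rng(7)
        )
        rng = np.random.default_rng(7)
        for r in range(5):
            literal = compute_curves(resample_tasks(tasks, rng), case1.descriptors, case1.grid)
            np.testing.assert_array_equal(ens.replicate_values[r], literal.values)

    def test_identical_tasks_collapse_to_base(self):
        t = TaskRecord("a", 0.0, 1.0, (("A", 0.0), ("B", 0.5)))
        ens = bootstrap_curves([t] * 10, ("A", "B"), TimeGrid.uniform(11), q=20, rng=1)
        assert (ens.replicate_values == ens.base_curves.values).all()

    def test_replicate_mean_matches_base(self, case1):
        tasks = simulate_population(case1, 60, np.random.default_rng(2))
        ens = bootstrap_curves(tasks, case1.descriptors, case1.grid, q=400, rng=3)
        # MC error of a mean of 400 resampled proportions
        tol = 4 * np.sqrt(0.25 / 60) / np.sqrt(400)
        assert np.abs(ens.replicate_values.mean(axis=0) - ens.base_curves.values).max() < 4 * tol

    def test_replicate_spread_is_binomial(self, case1):
        m, q = 100, 1000
        states = simulate_state_matrix(case1, m, np.random.default_rng(8))
        ens = ensemble_from_states(states, case1.descriptors, case1.grid, q, np.random.default_rng(9))
        d = ens.base_curves.values
        sd = ens.replicate_values.std(axis=0, ddof=1)
        mask = (d >= 0.2) & (d <= 0.8)
        theory = np.sqrt(d[mask] * (1 - d[mask]) / m)
        assert np.abs(sd[mask] / theory - 1).max() < 0.15

    def test_invalid_q_errors(self, case1):
        tasks = simulate_population(case1, 5, 0)
        with pytest.raises(TDSValidationError, match="q must be"):
            bootstrap_curves(tasks, case1.descriptors, case1.grid, q=0)


class TestOrderStatisticBands:
    def test_paper_ranks_at_q_1000(self):
        assert percentile_rank(1000, "ci95") == 25
        assert percentile_rank(1000, "se") == 159

    def test_rank_too_small_errors(self):
        with pytest.raises(TDSValidationError, match="too small"):
            percentile_rank(10, "ci95")

    def test_band_is_kth_order_statistic(self, rng):
        vals = np.repeat(
            rng.permutation(np.arange(1, 1001) / 1000.0).reshape(1000, 1, 1), 2, axis=2
        )
        ens = make_ensemble(vals)
        ci = band_from_order_statistics(ens, "ci95")
        assert (ci.lower[0, 0], ci.upper[0, 0]) == (0.025, 0.976)
        se = band_from_order_statistics(ens, "se")
        assert (se.lower[0, 0], se.upper[0, 0]) == (0.159, 0.842)

    def test_matches_counting_oracle_on_small_ensembles(self, rng):
        q = 50
        vals = rng.random((q, 2, 3))
        ens = make_ensemble(vals)
        for band in ("ci95", "se"):
            k = percentile_rank(q, band)
            got = band_from_order_statistics(ens, band)
            for j in range(2):
                for g in range(3):
                    col = vals[:, j, g]
                    assert got.lower[j, g] == kth_smallest_by_counting(col, k)
                    assert got.upper[j, g] == -kth_smallest_by_counting(-col, k)

    def test_tied_replicates_give_zero_width(self):
        ens = make_ensemble(np.full((200, 1, 2), 0.4))
        band = band_from_order_statistics(ens, "ci95")
        assert (band.lower == 0.4).all() and (band.upper == 0.4).all()

    def test_ci_contains_se_band(self, case1):
        tasks = simulate_population(case1, 80, np.random.default_rng(6))
        ens = bootstrap_curves(tasks, case1.descriptors, case1.grid, q=1000, rng=7)
        ci = band_from_order_statistics(ens, "ci95")
        se = band_from_order_statistics(ens, "se")
        assert (ci.lower <= se.lower).all() and (se.upper <= ci.upper).all()


class TestNormalBands:
    def test_ci95_halfwidth_arithmetic(self):
        cs = curves_from_states(np.array([[0, 0], [1, 1]]), ("A", "B"), TimeGrid.uniform(2))
        # d = 0.5 at both points
        band = normal_bands(cs, m=100, band="ci95")
        np.testing.assert_allclose(band.lower, 0.402)
        np.testing.assert_allclose(band.upper, 0.598)
        se = normal_bands(cs, m=100, band="se")
        np.testing.assert_allclose(se.halfwidth, 0.05)

    def test_degenerate_proportions_are_flagged(self):
        cs = curves_from_states(np.array([[0, 0]] * 10), ("A", "B"), TimeGrid.uniform(2))
        band = normal_bands(cs, m=50, band="ci95")
        assert (band.halfwidth[0] == 0).all() and (band.halfwidth[1] == 0).all()
        assert band.low_count_mask.all()

    def test_bounds_are_clipped_to_unit_interval(self):
        states = np.array([[0, 0]] * 1 + [[1, 1]] * 19)  # d_A = 0.05
        cs = curves_from_states(states, ("A", "B"), TimeGrid.uniform(2))
        band = normal_bands(cs, m=20, band="ci95")
        assert band.lower[0, 0] == 0.0
        assert band.low_count_mask[0, 0]  # m*d = 1 < 5

    def test_agrees_with_bootstrap_at_large_m(self, case1):
        m = 500
        states = simulate_state_matrix(case1, m, np.random.default_rng(10))
        ens = ensemble_from_states(
            states, case1.descriptors, case1.grid, 1000, np.random.default_rng(11)
        )
        boot = band_from_order_statistics(ens, "ci95").halfwidth
        norm = normal_bands(ens.base_curves, m, "ci95").halfwidth
        ref = exact_marginals(case1).values
        mask = (ref >= 0.2) & (ref <= 0.8)
        assert np.abs(boot[mask] / norm[mask] - 1).max() < 0.15
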