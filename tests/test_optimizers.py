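import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rugopt import (
    OptimizerConfig,
    SobolEngine,
    cma_update,
    hill_climb_center,
    projection_center,
    run_optimization,
    sample_cloud,
    select_parents,
)
from rugopt.optimizers import parent_count


class TestSelectParents:
    def test_full_fraction_keeps_everyone(self):
        idx = select_parents([1.0, 2.0, 3.0, 4.0], 1.0)
        assert sorted(idx) == [0, 1, 2, 3]

    def test_top_two_by_value(self):
        idx = select_parents([5.0, 1.0, 4.0, 2.0, 3.0], 0.4)
        assert list(idx) == [0, 2]

    def test_cutoff_tie_broken_by_lower_index(self):
        idx = select_parents([3.0, 3.0, 1.0], 0.34)
        assert list(idx) == [0]

    def test_minimum_one_parent(self):
        assert parent_count(50, 0.001) == 1
        assert parent_count(50, 0.2) == 10
        assert parent_count(5, 0.5) == 3  # half-up rounding of 2.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_parents([], 0.5)

    @settings(derandomize=True, max_examples=40)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(1, 60),
        frac=st.floats(0.01, 1.0),
    )
    def test_parents_dominate_non_parents(self, seed, n, frac):
        f = np.random.default_rng(seed).normal(size=n)
        idx = select_parents(f, frac)
        assert len(idx) == parent_count(n, frac)
        others = np.setdiff1d(np.arange(n), idx)
        if len(others):
            assert f[idx].min() >= f[others].max()


class TestCenterUpdates:
    def test_single_parent_is_its_own_center(self):
        assert np.array_equal(hill_climb_center([[3.0, 7.0]]), [3.0, 7.0])

    def test_midpoint_of_two_parents(self):
        assert np.array_equal(
            hill_climb_center([[0.0, 0.0], [2.0, 2.0]]), [1.0, 1.0]
        )

    def test_symmetric_parents_cancel(self):
        c = np.array([400.0, 600.0])
        offsets = np.array([[10, 5], [-10, -5], [3, -8], [-3, 8]], dtype=float)
        assert np.allclose(hill_climb_center(c + offsets), c)

    def test_projection_doubles_displacement(self):
        assert np.array_equal(
            projection_center([0.0, 0.0], [[1.0, 1.0]]), [2.0, 2.0]
        )
        assert np.array_equal(
            projection_center([100.0, 100.0], [[150.0, 100.0]]), [200.0, 100.0]
        )

    def test_projection_fixed_point_when_parents_centered(self):
        prev = np.array([5.0, -3.0])
        parents = prev + np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert np.array_equal(projection_center(prev, parents), prev)

    def test_projection_leaves_parent_hull(self):
        # the overshoot case: parents at x in [1, 3], previous center at 0,
        # projected center lands at 4, outside the parents' hull
        nxt = projection_center([0.0, 0.0], [[1.0, 0.0], [3.0, 0.0]])
        assert nxt[0] == 4.0


class TestCmaUpdate:
    def test_equal_fitness_gives_arithmetic_mean(self):
        parents = np.array([[0.0, 0.0], [4.0, 0.0], [2.0, 6.0]])
        center, _ = cma_update([1.0, 1.0], parents, [2.0, 2.0, 2.0], np.eye(2))
        assert np.allclose(center, parents.mean(axis=0))

    def test_weights_follow_fitness(self):
        parents = np.array([[0.0, 0.0], [10.0, 0.0]])
        center, _ = cma_update([0.0, 0.0], parents, [1.0, 3.0], np.eye(2))
        # worst parent is shifted to weight zero
        assert np.allclose(center, [10.0, 0.0])

    def test_shape_tracks_parent_anisotropy(self):
        rng = np.random.default_rng(0)
        parents = np.column_stack([rng.normal(0, 5, 40), rng.normal(0, 0.5, 40)])
        f = rng.uniform(1, 2, 40)
        _, shape = cma_update([0.0, 0.0], parents, f, np.eye(2))
        assert shape[0, 0] > shape[1, 1]

    def test_zero_shift_reduction_formula(self):
        parents = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        prev_shape = np.eye(2)
        center, shape = cma_update(
            [0.0, 0.0], parents, [1.0, 1.0, 1.0, 1.0], prev_shape,
            c_mu=0.5, c_1=0.0,
        )
        assert np.allclose(center, [0.0, 0.0])
        w = np.full(4, 0.25)
        cov = (parents * w[:, None]).T @ parents
        assert np.allclose(shape, 0.5 * prev_shape + 0.5 * cov)

    def test_shape_stays_spd_over_many_updates(self):
        rng = np.random.default_rng(5)
        shape = np.eye(2)
        center = np.zeros(2)
        for _ in range(100):
            parents = rng.normal(center, 2.0, size=(8, 2))
            f = rng.uniform(0, 1, 8)
            center, shape = cma_update(center, parents, f, shape, radius=2.0)
            assert np.allclose(shape, shape.T)
            assert np.linalg.eigvalsh(shape)[0] > 0

    def test_identical_parents_hit_ridge_floor(self, caplog):
        parents = np.tile([2.0, 2.0], (3, 1))
        with caplog.at_level("WARNING"):
            _, shape = cma_update([0.0, 0.0], parents, [1.0, 1.0, 1.0],
                                  np.eye(2) * 1e-12)
        assert np.linalg.eigvalsh(shape)[0] > 0

    def test_rank_weights_mode(self):
        parents = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        center, _ = cma_update([0.0, 0.0], parents, [3.0, 2.0, 1.0], np.eye(2),
                               weight_mode="rank")
        # best parent (index 0) gets the largest weight
        assert center[0] < parents[:, 0].mean()

    def test_too_few_parents_rejected(self):
        with pytest.raises(ValueError, match="2 parents"):
            cma_update([0.0, 0.0], [[1.0, 1.0]], [1.0], np.eye(2))


def base_config(**kw):
    defaults = dict(
        landscape_name="single",
        start_coordinates=(200.0, 200.0),
        sobol_radius=150.0,
        samples_per_iteration=50,
        parent_fraction=0.2,
        algorithm="hill_climb",
        seed=0,
        iterations=5,
    )
    defaults.update(kw)
    return OptimizerConfig(**defaults)


class TestConfigValidation:
    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError, match="parent_fraction"):
            base_config(parent_fraction=0.0)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            base_config(algorithm="simulated_annealing")

    def test_sc_outside_bounds_rejected(self, single_peak_landscape):
        cfg = base_config(start_coordinates=(-5.0, 200.0))
        with pytest.raises(ValueError, match="within the landscape bounds"):
            run_optimization(cfg, single_peak_landscape)


class TestRunOptimization:
    def test_single_iteration_centered_at_sc(self, single_peak_landscape):
        trace = run_optimization(base_config(iterations=1), single_peak_landscape)
        assert len(trace.iterations) == 1
        rec = trace.iterations[0]
        assert np.array_equal(rec.center, [200.0, 200.0])
        assert rec.center_fitness == single_peak_landscape.evaluate((200.0, 200.0))
        assert len(rec.samples) == 50

    @pytest.mark.parametrize("algorithm", ["hill_climb", "projection", "cma_es"])
    def test_same_seed_reproduces_trace_bitwise(self, algorithm, single_peak_landscape):
        cfg = base_config(algorithm=algorithm, seed=77)
        a = run_optimization(cfg, single_peak_landscape)
        b = run_optimization(cfg, single_peak_landscape)
        for ra, rb in zip(a.iterations, b.iterations):
            assert np.array_equal(ra.center, rb.center)
            assert np.array_equal(ra.samples, rb.samples)
            assert np.array_equal(ra.sample_fitnesses, rb.sample_fitnesses)
            assert np.array_equal(ra.parent_indices, rb.parent_indices)
        assert a.performance == b.performance

    @pytest.mark.parametrize("algorithm", ["hill_climb", "projection", "cma_es"])
    def test_parents_dominate_each_iteration(self, algorithm, model_trio):
        rugged = model_trio[2]
        cfg = base_config(algorithm=algorithm, start_coordinates=(300.0, 700.0),
                          landscape_name="rugged", seed=3)
        trace = run_optimization(cfg, rugged)
        assert len(trace.iterations) == 5
        for rec in trace.iterations:
            pid = rec.parent_indices
            others = np.setdiff1d(np.arange(len(rec.samples)), pid)
            assert rec.sample_fitnesses[pid].min() >= rec.sample_fitnesses[others].max()

    def test_hill_climb_center_in_parent_bounding_box(self, single_peak_landscape):
        cfg = base_config(seed=11)
        trace = run_optimization(cfg, single_peak_landscape)
        for prev, nxt in zip(trace.iterations, trace.iterations[1:]):
            parents = prev.samples[prev.parent_indices]
            assert np.all(nxt.center >= parents.min(axis=0) - 1e-9)
            assert np.all(nxt.center <= parents.max(axis=0) + 1e-9)

    def test_hill_climb_converges_to_single_peak(self, single_peak_landscape):
        """SC (200,200), sigma 150, n 50, I 5, F 0.2: at least 4 of 5 seeded
        replicates should finish within 50 units of the peak at (500,500)."""
        hits = 0
        for seed in range(5):
            trace = run_optimization(base_config(seed=seed), single_peak_landscape)
            final = trace.iterations[-1].center
            if np.linalg.norm(final - np.array([500.0, 500.0])) <= 50.0:
                hits += 1
        assert hits >= 4


class TestGradientResponse:
    """On a linear ramp, selection of the top half moves the center uphill;
    with F = 1 (no selection) the expected displacement vanishes."""

    @staticmethod
    def displacement(seed, fraction):
        center = np.zeros(2)
        cloud = sample_cloud(SobolEngine(2, seed=seed), center, 10.0, 64,
                             ((-1e6, 1e6), (-1e6, 1e6)))
        ramp = cloud.points[:, 0]  # fitness = x coordinate
        parents = cloud.points[select_parents(ramp, fraction)]
        return hill_climb_center(parents) - center

    def test_top_half_selection_climbs_the_ramp(self):
        moves = np.array([self.displacement(s, 0.5) for s in range(40)])
        assert np.all(moves[:, 0] > 0)
        assert abs(moves[:, 1].mean()) < 1.0

    def test_no_selection_means_no_drift(self):
        moves = np.array([self.displacement(s, 1.0) for s in range(40)])
        assert abs(moves[:, 0].mean()) < 1.0
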