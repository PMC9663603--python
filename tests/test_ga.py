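"""Stimulus-subset selection: fitness arithmetic, GA search, baselines."""

from itertools import combinations

import numpy as np
import pytest

from rsapipe import (
    GAConfig,
    RatingCatalog,
    SimSpec,
    assign_cell,
    enumerate_grid,
    fitness,
    gen_rating_catalog,
    random_baseline,
    run_ga,
)


def brute_force_optimum(catalog, config):
    """Enumeration oracle: minimum fitness over all subsets of the pool."""
    best = np.inf
    for combo in combinations(range(catalog.n_stimuli), config.subset_size):
        best = min(best, fitness(list(combo), catalog, config))
    return best


class TestGrid:
    @pytest.mark.parametrize("n_dims,expected", [(1, 2), (3, 8), (5, 32)])
    def test_cell_count_and_distinctness(self, n_dims, expected):
        cells = enumerate_grid(n_dims)
        assert len(cells) == expected
        assert len(set(cells)) == expected

    def test_binary_counting_order(self):
        labels = [c.label for c in enumerate_grid(2)]
        assert labels == ["00", "01", "10", "11"]

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid(0)

    @pytest.mark.parametrize(
        "ratings,bits",
        [
            ((3, -2, 0.5, -1, 7), (1, 0, 1, 0, 1)),
            ((0, 0, 0, 0, 0), (0, 0, 0, 0, 0)),  # boundary goes to the 0 pole
            ((10, 10, 10, 10, 10), (1, 1, 1, 1, 1)),
        ],
    )
    def test_assign_cell_sign_rule(self, ratings, bits):
        assert assign_cell(np.array(ratings, dtype=float)).bits == bits

    def test_assign_cell_missing_dimension_rejected(self):
        with pytest.raises(ValueError):
            assign_cell(np.array([1.0, np.nan]))


class TestFitness:
    def test_identical_dimension_columns_give_one(self, manual_catalog):
        # stimuli s0,s4,s5 have d0 == d1 -> |r| = 1; no constraint violations
        cfg = GAConfig(subset_size=3, penalty_weight=10.0, required_tags=())
        assert fitness(["s0", "s4", "s5"], manual_catalog, cfg) == pytest.approx(1.0)

    def test_orthogonal_sign_patterns_give_zero(self, manual_catalog):
        cfg = GAConfig(subset_size=4, penalty_weight=10.0, required_tags=())
        # (+1,+1),(+1,-1),(-1,+1),(-1,-1): orthogonal columns
        assert fitness(["s0", "s1", "s2", "s3"], manual_catalog, cfg) == pytest.approx(0.0)

    def test_category_violation_adds_penalty(self, manual_catalog):
        cfg = GAConfig(subset_size=4, penalty_weight=10.0, required_tags=(),
                       max_per_category=1)
        # s4,s5 share category c3 -> one violation on top of the base term
        base_cfg = GAConfig(subset_size=4, penalty_weight=0.0, required_tags=(),
                            max_per_category=1)
        base = fitness(["s0", "s1", "s4", "s5"], manual_catalog, base_cfg)
        full = fitness(["s0", "s1", "s4", "s5"], manual_catalog, cfg)
        assert full == pytest.approx(base + 10.0)

    def test_constant_dimension_treated_as_zero(self):
        ratings = np.array([[1.0, 2.0], [1.0, 5.0], [1.0, 3.0]])[None]
        cat = RatingCatalog(["a", "b", "c"], ["x", "y", "z"], ["d0", "d1"], ratings)
        cfg = GAConfig(subset_size=3, required_tags=())
        with pytest.warns(UserWarning, match="constant"):
            assert fitness(["a", "b", "c"], cat, cfg) == pytest.approx(0.0)


def _pool_catalog(seed, n_stimuli, n_categories=6):
    return gen_rating_catalog(SimSpec(seed=seed, n_stimuli=n_stimuli, n_dims=2,
                                      n_participants=2, n_categories=n_categories))


class TestRunGA:
    def test_attains_exhaustive_optimum_on_tiny_pool(self):
        cat = _pool_catalog(seed=21, n_stimuli=8)
        cfg = GAConfig(subset_size=4, n_generations=200, population_size=50,
                       required_tags=(), penalty_weight=0.0, seed=9)
        result = run_ga(cat, cfg)
        assert result.best_fitness == pytest.approx(brute_force_optimum(cat, cfg), abs=1e-12)

    def test_trace_non_increasing_with_elitism(self):
        cat = _pool_catalog(seed=22, n_stimuli=12)
        cfg = GAConfig(subset_size=5, n_generations=60, population_size=30,
                       elitism_count=1, required_tags=(), seed=3)
        trace = run_ga(cat, cfg).fitness_trace
        assert np.all(np.diff(trace) <= 0)

    def test_same_seed_same_subset(self):
        cat = _pool_catalog(seed=23, n_stimuli=15)
        cfg = GAConfig(subset_size=6, n_generations=40, population_size=20,
                       required_tags=(), seed=5)
        assert run_ga(cat, cfg).best_subset == run_ga(cat, cfg).best_subset

    def test_infeasible_required_tag_rejected(self):
        cat = _pool_catalog(seed=24, n_stimuli=10)
        cfg = GAConfig(subset_size=4, n_generations=10, population_size=10,
                       required_tags=("nonexistent tag",), seed=0)
        with pytest.raises(ValueError, match="nonexistent tag"):
            run_ga(cat, cfg)

    def test_constraints_satisfied_with_large_penalty(self):
        cat = gen_rating_catalog(SimSpec(seed=25, n_stimuli=30, n_dims=2,
                                         n_participants=2, n_categories=10))
        cfg = GAConfig(subset_size=8, n_generations=150, population_size=40,
                       penalty_weight=10.0, max_per_category=2, seed=2)
        result = run_ga(cat, cfg)
        labels = [cat.category_labels[cat.stimulus_ids.index(s)] for s in result.best_subset]
        _, counts = np.unique(labels, return_counts=True)
        assert counts.max() <= 2
        assert "human face" in labels and "human body" in labels

    def test_covered_cells_bounded(self):
        cat = _pool_catalog(seed=26, n_stimuli=12)
        cfg = GAConfig(subset_size=5, n_generations=30, population_size=20,
                       required_tags=(), seed=1)
        result = run_ga(cat, cfg)
        assert result.covered_cells <= min(5, 2**2)
        assert len(result.best_subset) == 5


class TestRandomBaseline:
    def test_single_draw_matches_unpenalized_fitness(self):
        cat = _pool_catalog(seed=27, n_stimuli=10)
        cfg = GAConfig(subset_size=4, n_random_baseline=1, required_tags=(),
                       penalty_weight=0.0, seed=8)
        vals = random_baseline(cat, cfg)
        assert vals.shape == (1,)
        rng = np.random.default_rng(8)
        idx = rng.choice(10, size=4, replace=False)
        assert vals[0] == pytest.approx(fitness(idx, cat, cfg))

    def test_degenerate_pool_zero_variance(self):
        cat = _pool_catalog(seed=28, n_stimuli=6)
        cfg = GAConfig(subset_size=6, n_random_baseline=5, required_tags=(), seed=0)
        vals = random_baseline(cat, cfg)
        assert np.ptp(vals) == 0

    def test_baseline_never_beats_brute_force(self):
        cat = _pool_catalog(seed=29, n_stimuli=9)
        cfg = GAConfig(subset_size=4, n_random_baseline=50, required_tags=(),
                       penalty_weight=0.0, seed=4)
        vals = random_baseline(cat, cfg)
        assert vals.min() >= brute_force_optimum(cat, cfg) - 1e-12
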