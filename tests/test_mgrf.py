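"""MG-RF: genome encoding, fitness with tree pruning, GA operators, and
the fitted regressor, with explicit per-tree averaging oracles."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor

from dentage.fusion import FeatureMatrix
from dentage.mgrf import (
    Chromosome,
    GAConfig,
    HyperGrid,
    decode_chromosome,
    encode_chromosome,
    evaluate_fitness,
    evolve_generation,
    fit_mgrf,
    init_population,
    predict_ages,
    rank_features,
)

SMALL_GRID = HyperGrid(max_depth=(5, 10), n_estimators=(20, 40))


def _regression_data(n, d, rng, noise=0.5):
    X = rng.normal(size=(n, d))
    y = 10.0 + 2.0 * X[:, 0] + noise * rng.normal(size=n)
    return X, y


def _tree_average_oracle(forest, X, retained):
    """Independent oracle: loop tree by tree, sum, divide."""
    total = np.zeros(X.shape[0])
    for i in retained:
        total += forest.estimators_[i].predict(X)
    return total / len(retained)


class TestRankFeatures:
    def test_planted_signal_column_ranked_first(self, rng):
        n = 500
        ages = rng.uniform(6, 15, n)
        X = rng.normal(size=(n, 10))
        X[:, 3] = ages + rng.normal(0, 0.3, n)  # noisy copy of the target
        order, scores = rank_features(X, ages, seed=0)
        assert order[0] == 3
        assert np.all(scores >= 0)
        assert scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_under_seed(self, rng):
        X, y = _regression_data(80, 5, rng)
        o1, s1 = rank_features(X, y, seed=3)
        o2, s2 = rank_features(X, y, seed=3)
        assert np.array_equal(o1, o2) and np.array_equal(s1, s2)

    def test_zero_width_matrix_rejected(self):
        with pytest.raises(ValueError, match="column"):
            rank_features(np.empty((5, 0)), np.zeros(5), seed=0)


class TestGenome:
    def test_decode_first_grid_entries(self):
        grid = HyperGrid()
        c = Chromosome((0, 0, 0, 0, 0), np.ones(grid.max_trees, bool))
        spec, retained = decode_chromosome(c, grid)
        assert spec == {"max_depth": 10, "max_features": "auto",
                        "min_samples_leaf": 1, "min_samples_split": 2,
                        "n_estimators": 200}
        assert retained.size == 200

    def test_decode_reference_best_configuration(self):
        # depth 10, sqrt mtry, leaf 4, split 10, 600 trees
        grid = HyperGrid()
        spec = {"max_depth": 10, "max_features": "sqrt", "min_samples_leaf": 4,
                "min_samples_split": 10, "n_estimators": 600}
        c = encode_chromosome(spec, np.ones(grid.max_trees, bool), grid)
        assert c.hyper_genes == (0, 1, 2, 2, 2)
        decoded, _ = decode_chromosome(c, grid)
        assert decoded == spec

    def test_decode_encode_identity_on_random_chromosomes(self, rng):
        grid = HyperGrid()
        for _ in range(20):
            genes = tuple(int(rng.integers(0, len(ax))) for ax in grid.axes)
            mask = rng.random(grid.max_trees) < 0.5
            c = Chromosome(genes, mask)
            spec, _ = decode_chromosome(c, grid)
            c2 = encode_chromosome(spec, mask, grid)
            assert c2.hyper_genes == c.hyper_genes
            assert np.array_equal(c2.tree_mask, c.tree_mask)

    def test_out_of_range_gene_rejected(self):
        grid = HyperGrid()
        c = Chromosome((99, 0, 0, 0, 0), np.ones(grid.max_trees, bool))
        with pytest.raises(ValueError, match="out of range"):
            decode_chromosome(c, grid)


class TestInitPopulation:
    def test_size_decode_closure_and_seed_sensitivity(self):
        grid, cfg = HyperGrid(), GAConfig(population_size=20)
        pop = init_population(cfg, grid, np.random.default_rng(0))
        assert len(pop) == 20
        for c in pop:
            spec, retained = decode_chromosome(c, grid)
            assert retained.size >= 1
        pop2 = init_population(cfg, grid, np.random.default_rng(1))
        assert any(a.key() != b.key() for a, b in zip(pop, pop2))

    def test_mask_off_gives_full_masks(self):
        cfg = GAConfig(optimize_tree_mask=False)
        pop = init_population(cfg, SMALL_GRID, np.random.default_rng(0))
        assert all(c.tree_mask.all() for c in pop)


class TestFitness:
    @pytest.fixture(scope="class")
    @classmethod
    def data(cls):
        rng = np.random.default_rng(7)
        X, y = _regression_data(80, 6, rng)
        return (X[:60], y[:60]), (X[60:], y[60:])

    def test_constant_target_gives_zero_fitness(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.full(40, 11.0)
        c = Chromosome((0, 0, 0, 0, 0), np.ones(SMALL_GRID.max_trees, bool))
        fit = evaluate_fitness(c, (X[:30], y[:30]), (X[30:], y[30:]),
                               SMALL_GRID, GAConfig())
        assert fit == pytest.approx(0.0, abs=1e-12)

    def test_masked_fitness_matches_per_tree_oracle(self, data, rng):
        (X_tr, y_tr), (X_val, y_val) = data
        mask = rng.random(SMALL_GRID.max_trees) < 0.5
        c = Chromosome((1, 1, 0, 0, 1), mask)
        spec, retained = decode_chromosome(c, SMALL_GRID)
        cfg = GAConfig(rng_seed=5)
        fit = evaluate_fitness(c, (X_tr, y_tr), (X_val, y_val), SMALL_GRID, cfg)
        forest = RandomForestRegressor(n_estimators=spec["n_estimators"],
                                       max_depth=spec["max_depth"],
                                       max_features="sqrt",
                                       min_samples_leaf=spec["min_samples_leaf"],
                                       min_samples_split=spec["min_samples_split"],
                                       random_state=5, n_jobs=1).fit(X_tr, y_tr)
        oracle_pred = _tree_average_oracle(forest, X_val, retained)
        assert fit == pytest.approx(float(np.mean((oracle_pred - y_val) ** 2)),
                                    abs=1e-9)

    def test_full_mask_equals_unpruned_forest_error(self, data):
        (X_tr, y_tr), (X_val, y_val) = data
        c = Chromosome((0, 1, 0, 0, 0), np.ones(SMALL_GRID.max_trees, bool))
        spec, _ = decode_chromosome(c, SMALL_GRID)
        cfg = GAConfig(rng_seed=2)
        fit = evaluate_fitness(c, (X_tr, y_tr), (X_val, y_val), SMALL_GRID, cfg)
        forest = RandomForestRegressor(n_estimators=spec["n_estimators"],
                                       max_depth=spec["max_depth"],
                                       max_features="sqrt",
                                       random_state=2, n_jobs=1).fit(X_tr, y_tr)
        unpruned = float(np.mean((forest.predict(X_val) - y_val) ** 2))
        assert fit == pytest.approx(unpruned, abs=1e-9)


class TestEvolve:
    def _pop(self, cfg, seed=0):
        rng = np.random.default_rng(seed)
        return init_population(cfg, SMALL_GRID, rng), rng

    def test_degenerate_operators_copy_parents(self):
        cfg = GAConfig(population_size=10, crossover_rate=0.0, mutation_rate=0.0)
        pop, rng = self._pop(cfg)
        fits = np.arange(10, dtype=float)
        children = evolve_generation(pop, fits, cfg, SMALL_GRID, rng)
        parent_keys = {c.key() for c in pop}
        assert all(c.key() in parent_keys for c in children)

    def test_elitism_keeps_best_verbatim(self):
        cfg = GAConfig(population_size=10, elitism=2)
        pop, rng = self._pop(cfg)
        fits = np.arange(10, dtype=float)[::-1]  # last is best
        children = evolve_generation(pop, fits, cfg, SMALL_GRID, rng)
        assert children[0].key() == pop[9].key()
        assert children[1].key() == pop[8].key()

    def test_population_size_preserved(self):
        cfg = GAConfig(population_size=9, elitism=1)
        for trial in range(30):
            pop, rng = self._pop(cfg, seed=trial)
            fits = np.random.default_rng(trial).random(9)
            assert len(evolve_generation(pop, fits, cfg, SMALL_GRID, rng)) == 9

    def test_high_mutation_changes_children(self):
        cfg = GAConfig(population_size=6, crossover_rate=0.0, mutation_rate=1.0)
        pop, rng = self._pop(cfg)
        children = evolve_generation(pop, np.arange(6, dtype=float), cfg,
                                     SMALL_GRID, rng)
        parent_keys = {c.key() for c in pop}
        # elite survives; every non-elite child differs from all parents
        assert all(c.key() not in parent_keys for c in children[1:])


class TestFitPredict:
    @pytest.fixture(scope="class")
    @classmethod
    def fitted(cls):
        rng = np.random.default_rng(11)
        X, y = _regression_data(120, 6, rng, noise=0.3)
        cfg = GAConfig(population_size=6, generations=4, rng_seed=0)
        model = fit_mgrf(X, y, cfg, SMALL_GRID)
        return model, X, y

    def test_history_best_nonincreasing_with_elitism(self, fitted):
        model, _, _ = fitted
        best = [h["best"] for h in model.ga_history]
        assert len(best) == 4
        assert all(b <= a for a, b in zip(best, best[1:]))

    def test_predictions_match_per_tree_oracle(self, fitted):
        model, X, _ = fitted
        pred = predict_ages(model, X[:20])
        oracle = _tree_average_oracle(model.forest, X[:20], model.retained)
        assert np.allclose(pred, oracle, atol=1e-9)
        # mean lies within the convex hull of per-tree predictions
        per_tree = np.stack([model.forest.estimators_[i].predict(X[:20])
                             for i in model.retained])
        assert np.all(pred >= per_tree.min(0) - 1e-12)
        assert np.all(pred <= per_tree.max(0) + 1e-12)

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(3)
        X, y = _regression_data(60, 4, rng)
        cfg = GAConfig(population_size=5, generations=3, rng_seed=9)
        p1 = predict_ages(fit_mgrf(X, y, cfg, SMALL_GRID), X)
        p2 = predict_ages(fit_mgrf(X, y, cfg, SMALL_GRID), X)
        assert np.array_equal(p1, p2)

    def test_empty_input_and_width_mismatch(self, fitted):
        model, X, _ = fitted
        assert predict_ages(model, np.empty((0, X.shape[1]))).size == 0
        with pytest.raises(ValueError, match="width"):
            predict_ages(model, X[:, :3])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_mgrf(np.zeros((5, 2)), np.zeros(5), GAConfig(), SMALL_GRID)

    def test_accepts_feature_matrix_container(self, fitted):
        model, X, y = fitted
        fm = FeatureMatrix(patient_ids=[f"P{i}" for i in range(20)],
                           values=X[:20], modality="fused")
        assert np.allclose(predict_ages(model, fm),
                           predict_ages(model, X[:20]), atol=1e-12)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"population_size": 1},
        {"crossover_rate": 1.5},
        {"mutation_rate": -0.1},
        {"tournament_size": 30},
        {"fitness_metric": "rmse"},
        {"generations": 0},
    ])
    def test_invalid_ga_config(self, kwargs):
        with pytest.raises(ValueError):
            GAConfig(**kwargs)

    def test_empty_grid_axis_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid(max_depth=())
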