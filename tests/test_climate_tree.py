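"""Evolutionary classification trees vs exhaustive and greedy baselines."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from trophoscape.climate_tree import (
    EvolutionConfig,
    TreeModel,
    TreeNode,
    evolve_tree,
    extract_thresholds,
    greedy_baseline,
    predict_tree,
)

SMALL_CFG = dict(population_size=60, generations=150, patience=150, tournament_size=4)


def checkerboard(
    n_per_quadrant: int = 25, noise_seed: int = 0, grid: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """XOR of two thresholds at 0.5.

    With ``grid=True`` the points form a symmetric lattice, so every single
    axis split leaves both sides exactly class-balanced (zero greedy gain);
    with random points finite-sample imbalance lets greedy shave a little.
    """
    pts, labels = [], []
    if grid:
        side = int(np.ceil(np.sqrt(n_per_quadrant)))
        base = np.array(list(itertools.product(np.linspace(0.05, 0.4, side), repeat=2)))
        for qx, qy in itertools.product([0, 1], repeat=2):
            pts.append(base + [qx * 0.55, qy * 0.55])
            labels += [qx ^ qy] * len(base)
    else:
        rng = np.random.default_rng(noise_seed)
        for qx, qy in itertools.product([0, 1], repeat=2):
            block = rng.uniform(0, 0.45, size=(n_per_quadrant, 2)) + [qx * 0.55, qy * 0.55]
            pts.append(block)
            labels += [qx ^ qy] * n_per_quadrant
    return np.vstack(pts), np.array(labels)


def exhaustive_depth2_optimum(X: np.ndarray, y: np.ndarray, cfg: EvolutionConfig) -> float:
    """Global fitness optimum over all depth<=2 trees with midpoint thresholds.

    The fitness (errors + alpha per leaf) decomposes over leaves, so the best
    depth-2 tree for a fixed root is the best depth-1 subtree on each side;
    the root is then enumerated exhaustively.
    """
    n = len(y)

    def leaf_err(idx):
        if len(idx) == 0:
            return 0
        counts = np.bincount(y[idx])
        return len(idx) - counts.max()

    def candidate_splits(idx):
        for var in range(X.shape[1]):
            u = np.unique(X[idx, var])
            for thr in (u[1:] + u[:-1]) / 2:
                left = idx[X[idx, var] < thr]
                right = idx[X[idx, var] >= thr]
                if len(left) >= cfg.min_samples_leaf and len(right) >= cfg.min_samples_leaf:
                    yield left, right

    def best_depth1(idx):
        # returns min over {leaf, single split} of (errors + alpha-per-leaf * n)
        best = leaf_err(idx) + cfg.alpha * n * 1
        for left, right in candidate_splits(idx):
            cost = leaf_err(left) + leaf_err(right) + cfg.alpha * n * 2
            best = min(best, cost)
        return best

    all_idx = np.arange(n)
    best = leaf_err(all_idx) + cfg.alpha * n * 1
    for left, right in candidate_splits(all_idx):
        best = min(best, best_depth1(left) + best_depth1(right))
    return best / n


class TestEvolveTree:
    def test_homogeneous_labels_single_leaf(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        model = evolve_tree(X, np.zeros(30, dtype=int), EvolutionConfig(seed=0, **SMALL_CFG))
        assert model.n_leaves == 1
        assert model.train_misclassification == 0.0

    def test_checkerboard_solved_globally(self):
        X, y = checkerboard()
        cfg = EvolutionConfig(seed=1, max_depth=2, min_samples_leaf=5, **SMALL_CFG)
        model = evolve_tree(X, y, cfg)
        assert model.train_misclassification == 0.0
        assert model.depth == 2

    def test_matches_exhaustive_optimum_on_tiny_instances(self):
        """Evolved fitness equals the exhaustive depth-2 global optimum in
        >= 9/10 seeded runs on small two-feature problems."""
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 1, size=(50, 2))
        y = ((X[:, 0] > 0.4) ^ (X[:, 1] > 0.6)).astype(int)
        flip = rng.random(50) < 0.1
        y[flip] ^= 1
        hits = 0
        for seed in range(10):
            cfg = EvolutionConfig(seed=seed, max_depth=2, min_samples_leaf=5, **SMALL_CFG)
            model = evolve_tree(X, y, cfg)
            optimum = exhaustive_depth2_optimum(X, y, cfg)
            assert model.fitness >= optimum - 1e-9
            hits += model.fitness <= optimum + 1e-9
        assert hits >= 9

    def test_fitness_history_monotone_non_increasing(self):
        X, y = checkerboard(noise_seed=3)
        model = evolve_tree(X, y, EvolutionConfig(seed=2, max_depth=3, **SMALL_CFG))
        assert all(a >= b - 1e-12 for a, b in zip(model.fitness_history, model.fitness_history[1:]))

    def test_leaf_class_ratios_sum_to_one(self):
        X, y = checkerboard(noise_seed=4)
        model = evolve_tree(X, y, EvolutionConfig(seed=0, max_depth=2, **SMALL_CFG))

        def walk(node: TreeNode):
            if node.is_leaf:
                assert node.class_ratio.sum() == pytest.approx(1.0)
            else:
                walk(node.left), walk(node.right)

        walk(model.root)

    def test_min_leaf_constraint_infeasible_rejected(self):
        with pytest.raises(ValueError):
            evolve_tree(np.zeros((6, 1)), np.arange(6) % 2, EvolutionConfig(min_samples_leaf=4))

    def test_deterministic_given_seed(self):
        X, y = checkerboard(noise_seed=5)
        cfg = EvolutionConfig(seed=9, max_depth=2, **SMALL_CFG)
        m1 = evolve_tree(X, y, cfg)
        m2 = evolve_tree(X, y, cfg)
        assert m1.fitness == m2.fitness
        assert extract_thresholds(m1).equals(extract_thresholds(m2))


class TestPredictTree:
    @staticmethod
    def one_split_model() -> TreeModel:
        root = TreeNode(var=0, threshold=5.0,
                        left=TreeNode(label=0), right=TreeNode(label=1))
        return TreeModel(root, ["x0"], ["low", "high"], 0.0, 0.0)

    def test_boundary_value_routes_right(self):
        model = self.one_split_model()
        assert predict_tree(model, np.array([[5.0]]))[0] == "high"
        assert predict_tree(model, np.array([[4.999]]))[0] == "low"

    def test_single_leaf_constant(self):
        model = TreeModel(TreeNode(label=0), ["x0"], ["only"], 0.0, 0.0)
        assert set(predict_tree(model, np.zeros((7, 1)))) == {"only"}

    def test_training_predictions_reproduce_stored_misclassification(self):
        X, y = checkerboard(noise_seed=6)
        model = evolve_tree(X, y, EvolutionConfig(seed=3, max_depth=2, **SMALL_CFG))
        pred = predict_tree(model, X)
        rate = np.mean(pred != y.astype(str))
        assert rate == pytest.approx(model.train_misclassification)

    def test_unknown_feature_column_rejected(self):
        model = self.one_split_model()
        with pytest.raises(KeyError):
            predict_tree(model, pd.DataFrame({"wrong": [1.0]}))


class TestExtractThresholds:
    def test_single_split_record(self):
        model = TestPredictTree.one_split_model()
        rep = extract_thresholds(model)
        assert len(rep) == 1
        assert rep.loc[0, "variable"] == "x0"
        assert rep.loc[0, "threshold"] == 5.0

    def test_single_leaf_empty_report(self):
        model = TreeModel(TreeNode(label=0), ["x0"], ["only"], 0.0, 0.0)
        assert len(extract_thresholds(model)) == 0

    def test_report_length_is_leaves_minus_one(self):
        X, y = checkerboard(noise_seed=7)
        model = evolve_tree(X, y, EvolutionConfig(seed=1, max_depth=3, **SMALL_CFG))
        assert len(extract_thresholds(model)) == model.n_leaves - 1


class TestGreedyBaseline:
    def test_matches_evolved_on_separable_problem(self):
        X = np.linspace(0, 1, 40)[:, None]
        y = (X[:, 0] > 0.5).astype(int)
        cfg = EvolutionConfig(seed=0, max_depth=2, min_samples_leaf=5, **SMALL_CFG)
        greedy = greedy_baseline(X, y, cfg)
        evolved = evolve_tree(X, y, cfg)
        assert greedy.train_misclassification == 0.0
        assert greedy.fitness == pytest.approx(evolved.fitness)

    def test_greedy_fails_checkerboard_where_evolution_succeeds(self):
        """The known greedy failure mode: no single split improves the XOR
        pattern, so greedy stops at the root while evolution solves it."""
        X, y = checkerboard(grid=True)
        cfg = EvolutionConfig(seed=0, max_depth=2, min_samples_leaf=5, **SMALL_CFG)
        greedy = greedy_baseline(X, y, cfg)
        evolved = evolve_tree(X, y, cfg)
        assert evolved.train_misclassification <= greedy.train_misclassification
        assert evolved.fitness <= greedy.fitness + 1e-12
        assert greedy.train_misclassification == 0.5
        assert evolved.train_misclassification == 0.0

    def test_evolved_never_worse_than_greedy_across_seeds(self):
        wins = 0
        for seed in range(10):
            X, y = checkerboard(noise_seed=seed)
            cfg = EvolutionConfig(seed=seed, max_depth=2, min_samples_leaf=5, **SMALL_CFG)
            wins += evolve_tree(X, y, cfg).fitness <= greedy_baseline(X, y, cfg).fitness + 1e-12
        assert wins >= 10 * 0.95

    def test_min_leaf_respected_everywhere(self):
        X, y = checkerboard(noise_seed=8)
        cfg = EvolutionConfig(seed=0, max_depth=3, min_samples_leaf=7, **SMALL_CFG)
        for model in (greedy_baseline(X, y, cfg), evolve_tree(X, y, cfg)):

            def walk(node: TreeNode):
                if node.is_leaf:
                    assert node.n_samples >= 7
                else:
                    walk(node.left), walk(node.right)

            walk(model.root)

    def test_agrees_with_sklearn_on_separable_problem(self):
        """Independent cross-check: on a one-threshold problem, the greedy split
        matches sklearn's CART within the data gap."""
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 10, size=(200, 1))
        y = (X[:, 0] >= 6.2).astype(int)
        cfg = EvolutionConfig(seed=0, max_depth=1, min_samples_leaf=2, **SMALL_CFG)
        greedy = greedy_baseline(X, y, cfg)
        sk = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        assert greedy.root.threshold == pytest.approx(sk.tree_.threshold[0], abs=0.1)
        assert greedy.train_misclassification == 0.0


def test_tree_model_json_roundtrip(tmp_path):
    X, y = checkerboard(noise_seed=10)
    model = evolve_tree(X, y, EvolutionConfig(seed=4, max_depth=2, **SMALL_CFG))
    path = tmp_path / "tree.json"
    model.to_json(path)
    back = TreeModel.from_json(path)
    assert np.array_equal(predict_tree(back, X), predict_tree(model, X))
    assert back.train_misclassification == model.train_misclassification
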