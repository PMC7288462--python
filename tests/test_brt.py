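import itertools

import numpy as np
import pytest

from musselpipe import brt
from musselpipe.datamodel import DataError


def brute_force_best_split(x, z):
    """Exhaustive search over all thresholds of one numeric feature."""
    best = (-np.inf, None)
    n = len(z)
    total = z.sum()
    for t in np.unique(x)[:-1]:
        left = x <= t
        nl = left.sum()
        gain = (
            z[left].sum() ** 2 / nl
            + (total - z[left].sum()) ** 2 / (n - nl)
            - total**2 / n
        )
        if gain > best[0]:
            best = (gain, t)
    return best


class TestFitTree:
    def test_perfect_binary_separator(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        z = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        tree = brt.fit_tree(z, X, depth=1, min_node_size=1)
        pred = tree.predict(X)
        np.testing.assert_allclose(pred, z)
        assert len(tree.splits) == 1

    def test_constant_target_single_leaf(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        z = np.full(10, 0.7)
        tree = brt.fit_tree(z, X, depth=2, min_node_size=1)
        assert len(tree.nodes) == 1
        np.testing.assert_allclose(tree.predict(X), 0.7)

    def test_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(30, 2))
            z = rng.normal(size=30)
            tree = brt.fit_tree(z, X, depth=1, min_node_size=1)
            if not tree.splits:
                continue
            f, gain = tree.splits[0]
            want = max(
                brute_force_best_split(X[:, 0], z)[0],
                brute_force_best_split(X[:, 1], z)[0],
            )
            assert gain == pytest.approx(want, abs=1e-9)

    def test_categorical_ordered_mean_split(self):
        # levels 0/2 low, 1/3 high: subset split must group them correctly
        X = np.array([[c] for c in [0, 0, 1, 1, 2, 2, 3, 3]], dtype=float)
        z = np.array([-1, -1, 1, 1, -1, -1, 1, 1], dtype=float)
        tree = brt.fit_tree(z, X, depth=1, min_node_size=1, cat_features={0})
        node = tree.nodes[0]
        assert node.cats_left in ({0.0, 2.0}, {1.0, 3.0}) or node.cats_left in (
            frozenset({0.0, 2.0}), frozenset({1.0, 3.0}),
        )
        np.testing.assert_allclose(tree.predict(X), z)


class TestFitBrt:
    def test_constant_response_intercept_only(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.ones(20, dtype=int)
        model = brt.fit_brt(X, y, "bernoulli", brt.BRTConfig(
            learning_rate=0.1, max_trees=10, cv_folds=2, seed=0))
        assert model.warnings_
        assert len(model.trees) == 0
        proba, _ = brt.predict(model, X)
        np.testing.assert_allclose(proba[:, 1], 1.0, atol=1e-6)

    def test_training_deviance_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=120) > 0).astype(int)
        cfg = brt.BRTConfig(
            learning_rate=0.05, max_trees=60, cv_folds=2, bag_fraction=1.0,
            min_node_size=5, seed=0,
        )
        model = brt.fit_brt(X, y, "bernoulli", cfg)
        devs = [
            brt.deviance("bernoulli", y, model.predict_proba(X, n_trees=t))
            for t in range(0, 61, 5)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(devs, devs[1:]))
        assert devs[-1] < devs[0]

    def test_strong_predictor_matches_logistic_oracle(self):
        """Single binary predictor: boosted probabilities converge to the
        class-conditional frequencies (the saturated logistic fit)."""
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.integers(0, 2, n)
        p = np.where(x == 1, 0.8, 0.2)
        y = rng.binomial(1, p)
        X = x.reshape(-1, 1).astype(float)
        cfg = brt.BRTConfig(
            learning_rate=0.1, max_trees=200, cv_folds=2, bag_fraction=1.0,
            tree_depth=1, seed=0,
        )
        model = brt.fit_brt(X, y, "bernoulli", cfg)
        proba, _ = brt.predict(model, np.array([[0.0], [1.0]]))
        assert proba[0, 1] == pytest.approx(y[x == 0].mean(), abs=0.02)
        assert proba[1, 1] == pytest.approx(y[x == 1].mean(), abs=0.02)

    def test_multinomial_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(90, 2))
        y = rng.integers(0, 3, 90)
        cfg = brt.BRTConfig(learning_rate=0.1, max_trees=30, cv_folds=2, seed=0)
        model = brt.fit_brt(X, y, "multinomial", cfg)
        proba, _ = brt.predict(model, X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


class TestCvSelectTrees:
    def test_noise_selects_few_trees_and_r2_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        y = rng.integers(0, 2, 200)
        cfg = brt.BRTConfig(
            learning_rate=0.05, max_trees=120, cv_folds=5,
            min_trees_guideline=10, seed=0,
        )
        with pytest.warns(UserWarning):
            n_opt, curve, pred = brt.cv_select_trees(X, y, "bernoulli", cfg)
        r2 = brt.pseudo_r2(pred, y)
        assert n_opt < 60
        assert r2 < 0.1

    def test_signal_beats_null_deviance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        cfg = brt.BRTConfig(
            learning_rate=0.1, max_trees=150, cv_folds=5,
            min_trees_guideline=10, seed=0,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_opt, curve, pred = brt.cv_select_trees(X, y, "bernoulli", cfg)
        assert curve[n_opt] < curve[0]
        assert brt.pseudo_r2(pred, y) > 0.8

    def test_fold_assignment_reproducible(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, 60)
        cfg = brt.BRTConfig(learning_rate=0.1, max_trees=20, cv_folds=4,
                            min_trees_guideline=1, seed=9)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = brt.cv_select_trees(X, y, "bernoulli", cfg)
            b = brt.cv_select_trees(X, y, "bernoulli", cfg)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[2], b[2])

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError):
            brt.cv_select_trees(
                np.zeros((3, 1)), np.array([0, 1, 0]), "bernoulli",
                brt.BRTConfig(cv_folds=5, max_trees=10),
            )


class TestPredict:
    def test_map_is_argmax_with_lowest_index_tie_break(self):
        proba = np.array([[0.3, 0.36, 0.34], [0.5, 0.5, 0.0]])
        assert proba.argmax(axis=1).tolist() == [1, 0]

    def test_intercept_only_predicts_training_mean(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 2))
        y = rng.binomial(1, 0.3, 50)
        model = brt.fit_brt(X, y, "bernoulli", brt.BRTConfig(
            learning_rate=0.1, max_trees=10, cv_folds=2, seed=0), n_trees=0)
        proba, _ = brt.predict(model, X)
        np.testing.assert_allclose(proba[:, 1], y.mean(), atol=1e-9)

    def test_feature_count_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, 30)
        model = brt.fit_brt(X, y, "bernoulli", brt.BRTConfig(
            learning_rate=0.1, max_trees=5, cv_folds=2, seed=0))
        with pytest.raises(DataError):
            brt.predict(model, np.zeros((3, 5)))


class TestPseudoR2:
    def test_equal_errors_zero(self):
        y = np.array([0, 0, 0, 1, 1])
        pred = np.array([0, 0, 0, 0, 0])  # err_M = 0.4 = err_0
        assert brt.pseudo_r2(pred, y) == pytest.approx(0.0)

    def test_perfect_predictions_one(self):
        y = np.array([0, 1, 1, 0])
        assert brt.pseudo_r2(y, y) == pytest.approx(1.0)

    def test_stated_ratio(self):
        # err_0 = 0.4, err_M = 0.2 -> 0.5
        y = np.array([0, 0, 0, 1, 1, 0, 0, 0, 1, 1])
        pred = np.array([0, 0, 0, 1, 0, 0, 0, 0, 1, 0])
        assert brt.pseudo_r2(pred, y) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        y = np.zeros(5, dtype=int)
        assert np.isnan(brt.pseudo_r2(y, y))


class TestRelativeInfluence:
    def test_single_driver_dominates(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 4))
        y = (X[:, 2] > 0).astype(int)
        model = brt.fit_brt(X, y, "bernoulli", brt.BRTConfig(
            learning_rate=0.1, max_trees=80, cv_folds=2, seed=0))
        infl = brt.relative_influence(model)
        assert infl[2] > 90
        assert infl.sum() == pytest.approx(100.0)

    def test_duplicated_column_shares_influence(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=400)
        y = (x > 0).astype(int)
        X1 = x.reshape(-1, 1)
        X2 = np.column_stack([x, x])
        cfg = brt.BRTConfig(learning_rate=0.1, max_trees=60, cv_folds=2,
                            bag_fraction=0.5, seed=0)
        m1 = brt.fit_brt(X1, y, "bernoulli", cfg)
        m2 = brt.fit_brt(X2, y, "bernoulli", cfg)
        i1 = brt.relative_influence(m1)
        i2 = brt.relative_influence(m2)
        assert i1[0] == pytest.approx(100.0)
        assert i2.sum() == pytest.approx(100.0)

    def test_intercept_only_all_zero(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 2))
        model = brt.fit_brt(X, np.ones(20, dtype=int), "bernoulli",
                            brt.BRTConfig(learning_rate=0.1, max_trees=5,
                                          cv_folds=2, seed=0))
        assert brt.relative_influence(model).sum() == 0.0


class TestPartialDependence:
    def test_intercept_only_flat_at_training_mean(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 2))
        y = rng.binomial(1, 0.25, 40)
        model = brt.fit_brt(X, y, "bernoulli", brt.BRTConfig(
            learning_rate=0.1, max_trees=5, cv_folds=2, seed=0), n_trees=0)
        curve = brt.partial_dependence(model, 0, np.linspace(-2, 2, 11))
        np.testing.assert_allclose(curve, y.mean(), atol=1e-9)

    def test_monotone_single_predictor_monotone_curve(self):
        rng = np.random.default_rng(13)
        x = np.sort(rng.uniform(0, 10, 300))
        y = (x > 5).astype(int)
        model = brt.fit_brt(x.reshape(-1, 1), y, "bernoulli", brt.BRTConfig(
            learning_rate=0.1, max_trees=100, cv_folds=2, tree_depth=1,
            bag_fraction=1.0, seed=0))
        curve = brt.partial_dependence(model, 0, np.linspace(0, 10, 21))
        assert np.all(np.diff(curve) >= -1e-9)

    def test_empty_grid_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 1))
        y = rng.integers(0, 2, 30)
        model = brt.fit_brt(X, y, "bernoulli", brt.BRTConfig(
            learning_rate=0.1, max_trees=5, cv_folds=2, seed=0))
        with pytest.raises(DataError):
            brt.partial_dependence(model, 0, [])
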