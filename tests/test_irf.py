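"""Trees, forests, iRF, decision paths and random intersection trees.

The central oracles: an exhaustive search over all (feature, midpoint)
splits for tree nodes, an independent recursive traversal for path
extraction, and a brute-force subset enumeration for RIT prevalences.
"""

import itertools

import numpy as np
import pytest

from neurochemnet.irf import (
    FeaturePath,
    ForestParams,
    IterativeRandomForest,
    RITParams,
    extract_paths,
    fit_forest,
    fit_irf,
    fit_tree,
    path_prevalence,
    random_intersection_trees,
    stability_interactions,
    tree_predict,
)


def gini(y):
    counts = np.bincount(y)
    return 1.0 - ((counts / len(y)) ** 2).sum()


def exhaustive_best_split(X, y, task, min_leaf):
    """Brute force over every feature and every midpoint threshold."""
    n, p = X.shape
    imp = gini(y) if task == "classification" else np.var(y)
    best = None  # (decrease, feature, threshold)
    for f in range(p):
        for thr in np.unique(X[:, f]):
            pass
        xs = np.unique(X[:, f])
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = (lo + hi) / 2.0
            left = X[:, f] <= thr
            nl, nr = left.sum(), (~left).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            if task == "classification":
                child = (nl * gini(y[left]) + nr * gini(y[~left])) / n
            else:
                child = (nl * np.var(y[left]) + nr * np.var(y[~left])) / n
            dec = imp - child
            if best is None or dec > best[0] + 1e-12:
                best = (dec, f, thr)
    return best


class TestTreeSplits:
    @pytest.mark.parametrize("task", ["classification", "regression"])
    @pytest.mark.parametrize("seed", range(25))
    def test_root_split_equals_exhaustive_oracle(self, task, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 14))
        p = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p)).round(1)  # rounding forces ties
        if task == "classification":
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
        else:
            y = rng.normal(size=n)
        params = ForestParams(mtry=p, min_leaf=1, max_depth=1)
        tree = fit_tree(X, y, task=task, params=params, rng=np.random.default_rng(0))
        oracle = exhaustive_best_split(X, y, task, 1)
        if oracle is None or oracle[0] <= 1e-12:
            assert tree.is_leaf
            return
        assert not tree.is_leaf
        n_l, n_r = tree.left.n_samples, tree.right.n_samples
        ours = tree.impurity - (
            n_l * tree.left.impurity + n_r * tree.right.impurity
        ) / tree.n_samples
        assert ours == pytest.approx(oracle[0], abs=1e-10)

    def test_constant_response_gives_single_leaf(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        tree = fit_tree(X, np.zeros(10, dtype=int), rng=np.random.default_rng(0))
        assert tree.is_leaf

    def test_separable_one_dimensional_split_at_zero(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        tree = fit_tree(X, y, rng=np.random.default_rng(0))
        assert tree.threshold == pytest.approx(0.0)
        pred = np.argmax(tree_predict(tree, X, n_classes=2), axis=1)
        assert np.array_equal(pred, y)

    def test_tie_break_prefers_lowest_feature_index(self):
        # identical duplicated feature: both give the same decrease
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        X = np.column_stack([x, x])
        y = np.array([0, 0, 1, 1])
        tree = fit_tree(
            X, y, params=ForestParams(mtry=2, min_leaf=1), rng=np.random.default_rng(0)
        )
        assert tree.feature == 0

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, 30)
        params = ForestParams(mtry=2, min_leaf=5)
        tree = fit_tree(X, y, params=params, rng=rng)

        def leaves(node):
            if node.is_leaf:
                yield node
            else:
                yield from leaves(node.left)
                yield from leaves(node.right)

        assert all(leaf.n_samples >= 5 for leaf in leaves(tree))

    def test_all_zero_weights_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="weights"):
            fit_tree(X, np.array([0, 1, 0, 1]), feature_weights=np.zeros(2))

    def test_zero_weight_feature_never_used(self, rng):
        X = rng.normal(size=(50, 2))
        y = (X[:, 1] > 0).astype(int)  # only the zero-weight feature is informative
        tree = fit_tree(
            X, y, feature_weights=np.array([1.0, 0.0]),
            params=ForestParams(mtry=2, min_leaf=1), rng=rng,
        )

        def features_used(node):
            if node.is_leaf:
                return set()
            return {node.feature} | features_used(node.left) | features_used(node.right)

        assert 1 not in features_used(tree)


class TestForest:
    def test_single_feature_importance_is_one(self, rng):
        X = rng.normal(size=(40, 1))
        y = (X[:, 0] > 0).astype(int)
        forest = fit_forest(X, y, params=ForestParams(n_trees=10), rng=rng)
        assert forest.importances_ == pytest.approx([1.0])

    def test_importance_normalized_and_planted_signal_wins(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 8))
            y = X[:, 0]  # exact copy: regression target
            forest = fit_forest(
                X, y, task="regression", params=ForestParams(n_trees=25), rng=rng
            )
            assert forest.importances_.sum() == pytest.approx(1.0)
            hits += int(np.argmax(forest.importances_) == 0)
        assert hits == 20

    def test_pure_noise_importance_stays_diffuse(self):
        ok = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(60, 8))
            y = rng.permutation(np.repeat([0, 1], 30))
            forest = fit_forest(X, y, params=ForestParams(n_trees=30), rng=rng)
            ok += int(forest.importances_.max() <= 0.35)
        assert ok >= 27

    def test_bootstrap_determinism_bit_stable(self, rng):
        X = np.random.default_rng(5).normal(size=(50, 4))
        y = (X[:, 1] + X[:, 2] > 0).astype(int)
        f1 = fit_forest(X, y, params=ForestParams(n_trees=12), rng=np.random.default_rng(77))
        f2 = fit_forest(X, y, params=ForestParams(n_trees=12), rng=np.random.default_rng(77))
        assert np.array_equal(f1.predict_proba(X), f2.predict_proba(X))
        assert np.array_equal(f1.importances_, f2.importances_)
        assert all(np.array_equal(a, b) for a, b in zip(f1.bootstrap_indices, f2.bootstrap_indices))

    def test_regression_never_worse_than_mean_predictor(self, rng):
        X = rng.normal(size=(80, 3))
        y = X[:, 0] + 0.5 * rng.normal(size=80)
        forest = fit_forest(X, y, task="regression", params=ForestParams(n_trees=30), rng=rng)
        mse = float(np.mean((forest.predict(X) - y) ** 2))
        assert mse <= float(np.var(y))

    def test_mtry_clamped_with_warning(self, rng):
        X = rng.normal(size=(20, 2))
        y = (X[:, 0] > 0).astype(int)
        with pytest.warns(UserWarning, match="clamping"):
            fit_forest(X, y, params=ForestParams(n_trees=2, mtry=10), rng=rng)

    def test_agrees_with_sklearn_on_dominant_feature(self, rng):
        # independent cross-check: scikit-learn's forest ranks the same
        # feature first on strongly planted data
        from sklearn.ensemble import RandomForestRegressor

        X = rng.normal(size=(150, 5))
        y = 2.0 * X[:, 3] + 0.1 * rng.normal(size=150)
        ours = fit_forest(X, y, task="regression", params=ForestParams(n_trees=40), rng=rng)
        ref = RandomForestRegressor(n_estimators=40, random_state=0).fit(X, y)
        assert np.argmax(ours.importances_) == np.argmax(ref.feature_importances_) == 3


class TestIRF:
    def test_single_iteration_identical_to_plain_forest(self, rng):
        X = np.random.default_rng(2).normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        model = fit_irf(X, y, n_iterations=1, params=ForestParams(n_trees=8),
                        rng=np.random.default_rng(9))
        forest = fit_forest(X, y, feature_weights=np.full(4, 0.25),
                            params=ForestParams(n_trees=8), rng=np.random.default_rng(9))
        assert np.array_equal(model.importances_, forest.importances_)
        assert np.array_equal(model.forest.predict_proba(X), forest.predict_proba(X))

    def test_final_importance_sums_to_one(self, rng):
        X = rng.normal(size=(60, 5))
        y = X[:, 1] + rng.normal(size=60)
        model = fit_irf(X, y, task="regression", n_iterations=3,
                        params=ForestParams(n_trees=15), rng=rng)
        assert model.importances_.sum() == pytest.approx(1.0)
        assert np.allclose(model.weights[0], 0.2)

    def test_iteration_concentrates_signal_importance(self):
        # y = x1 + noise: mean importance of x1 rises from K=1 to K=3
        first, last = [], []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 8))
            y = X[:, 0] + 0.7 * rng.normal(size=100)
            model = fit_irf(X, y, task="regression", n_iterations=3,
                            params=ForestParams(n_trees=20), rng=rng)
            first.append(model.forests[0].importances_[0])
            last.append(model.forests[-1].importances_[0])
        assert np.mean(last) > np.mean(first)

    def test_model_object_facade(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 2] > 0).astype(int)
        res = IterativeRandomForest(
            X, y, task="classification", n_iterations=2,
            params=ForestParams(n_trees=10), feature_names=["a", "b", "c"],
        ).fit(seed=4)
        assert res.importance_series().index[0] == "c"
        assert "feature importance" in res.summary()
        assert res.predict(X).shape == (60,)


class TestPaths:
    def test_single_leaf_tree_contributes_no_paths(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.zeros(10, dtype=int)
        forest = fit_forest(X, y, params=ForestParams(n_trees=5), rng=rng)
        assert extract_paths(forest) == []

    def test_depth_one_tree_gives_two_singleton_paths(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        forest = fit_forest(
            X, y, params=ForestParams(n_trees=1, max_depth=1), rng=np.random.default_rng(0)
        )
        paths = extract_paths(forest)
        assert len(paths) == 2
        assert all(p.features == frozenset({0}) for p in paths)

    def test_class_filter_keeps_only_that_class(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        forest = fit_forest(X, y, params=ForestParams(n_trees=1, max_depth=1),
                            rng=np.random.default_rng(0))
        paths = extract_paths(forest, class_filter=1)
        assert len(paths) == 1
        assert paths[0].label == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_traversal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 4))
        y = (X[:, 0] + X[:, 2] > 0).astype(int)
        forest = fit_forest(X, y, params=ForestParams(n_trees=5), rng=rng)
        paths = extract_paths(forest)

        oracle = []
        for tree in forest.trees:
            stack = [(tree, frozenset())]
            while stack:
                node, acc = stack.pop()
                if node.is_leaf:
                    if acc:
                        oracle.append((acc, node.n_samples))
                else:
                    stack.append((node.left, acc | {node.feature}))
                    stack.append((node.right, acc | {node.feature}))
        key = lambda t: (sorted(t[0]), t[1])  # noqa: E731
        assert sorted(((p.features, p.weight) for p in paths), key=key) == sorted(
            ((f, float(w)) for f, w in oracle), key=key
        )


class TestRIT:
    def test_identical_paths_survive_with_prevalence_one(self, rng):
        s = frozenset({1, 3})
        paths = [FeaturePath(s, 2.0) for _ in range(6)]
        found = random_intersection_trees(paths, RITParams(n_rit_trees=10, depth=3), rng)
        assert set(found) == {s}
        assert found[s] == 1.0

    def test_depth_zero_returns_sampled_root_sets(self, rng):
        paths = [
            FeaturePath(frozenset({0, 1}), 1.0),
            FeaturePath(frozenset({2, 3}), 1.0),
        ]
        found = random_intersection_trees(
            paths, RITParams(n_rit_trees=50, depth=0, min_size=2), rng
        )
        assert set(found) <= {frozenset({0, 1}), frozenset({2, 3})}
        assert len(found) == 2  # both sampled at least once in 50 trees

    def test_prevalences_match_brute_force_enumeration(self, rng):
        # 10 hand-built paths over 4 features with varying weights
        paths = [
            FeaturePath(frozenset(f), float(w))
            for f, w in [
                ((0, 1), 3), ((0, 1), 1), ((0, 1, 2), 2), ((1, 2), 1), ((0, 2), 1),
                ((0, 1, 3), 2), ((2, 3), 1), ((0, 3), 1), ((1, 3), 1), ((0, 1, 2, 3), 2),
            ]
        ]
        total = sum(p.weight for p in paths)
        found = random_intersection_trees(
            paths, RITParams(n_rit_trees=200, depth=4, n_child=2), rng
        )
        assert found  # something survives
        for s, prevalence in found.items():
            oracle = sum(p.weight for p in paths if s <= p.features) / total
            assert prevalence == pytest.approx(oracle)
            assert len(s) >= 2
        # the dominant pair {0, 1} (prevalence 10/15) must be recovered
        assert frozenset({0, 1}) in found

    def test_empty_paths_rejected(self, rng):
        with pytest.raises(ValueError):
            random_intersection_trees([], rng=rng)

    def test_prevalence_helper_weighted(self):
        paths = [FeaturePath(frozenset({0, 1}), 3.0), FeaturePath(frozenset({1}), 1.0)]
        assert path_prevalence(paths, frozenset({0, 1})) == pytest.approx(0.75)


class TestStabilityInteractions:
    def test_two_bags_give_discrete_stability(self, rng):
        X = np.random.default_rng(0).normal(size=(80, 4))
        y = ((X[:, 0] > 0) & (X[:, 1] > 0)).astype(int)
        out = stability_interactions(
            X, y, n_iterations=1, params=ForestParams(n_trees=5),
            rit=RITParams(n_rit_trees=20, depth=3), n_bags=2, rng=rng,
        )
        assert all(i.stability in (0.5, 1.0) for i in out)

    def test_planted_pairwise_interaction_recovered(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 8))
            y = ((X[:, 0] > 0) & (X[:, 1] > 0)).astype(int)
            out = stability_interactions(
                X, y, n_iterations=2, params=ForestParams(n_trees=30),
                rit=RITParams(n_rit_trees=50, depth=4), n_bags=5,
                class_filter=1, rng=rng,
            )
            stable = {i.features for i in out if i.stability >= 0.5}
            hits += int(frozenset({0, 1}) in stable)
        assert hits >= 4

    def test_pure_noise_yields_no_stable_interaction(self):
        clean = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(100, 8))
            y = rng.permutation(np.repeat([0, 1], 50))
            out = stability_interactions(
                X, y, n_iterations=2, params=ForestParams(n_trees=20),
                rit=RITParams(n_rit_trees=50, depth=4), n_bags=5, rng=rng,
            )
            clean += int(not any(i.stability >= 0.5 for i in out))
        assert clean >= 4
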