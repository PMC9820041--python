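"""Regression forest, MDG importance, fit metrics, GWR, data splits."""

import numpy as np
import pandas as pd
import pytest

from activitygrid.models import (GWR, ForestConfig, RegressionTree,
                                 VarianceImpurityForest, adjusted_r2,
                                 compare_models, mdg_importance, mse, r2,
                                 split_data)


class TestSplitData:
    def test_study_fractions_on_100(self):
        tr, te, va = split_data(100, seed=0)
        assert (len(tr), len(te), len(va)) == (55, 30, 15)

    def test_deterministic_under_seed(self):
        a = split_data(20, seed=9)
        b = split_data(20, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_partition_property(self, rng):
        for n in rng.integers(10, 5000, size=50):
            tr, te, va = split_data(int(n), seed=int(n))
            allidx = np.concatenate([tr, te, va])
            assert len(allidx) == n
            assert len(np.unique(allidx)) == n

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_data(2)


class TestMetrics:
    def test_hand_evaluated_example(self):
        y, yhat = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        assert abs(mse(y, yhat) - 1 / 3) < 1e-12
        assert abs(r2(y, yhat) - 0.5) < 1e-12
        assert abs(adjusted_r2(y, yhat, k=1) - 0.0) < 1e-12

    def test_perfect_prediction(self):
        y = [1.0, 5.0, 2.0, 8.0]
        assert mse(y, y) == 0.0
        assert r2(y, y) == 1.0
        assert adjusted_r2(y, y, k=2) == 1.0

    def test_closed_form_agreement_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            y = rng.normal(size=n)
            yhat = y + rng.normal(scale=0.5, size=n)
            sse = np.sum((y - yhat) ** 2)
            sst = np.sum((y - y.mean()) ** 2)
            assert abs(mse(y, yhat) - sse / n) < 1e-12
            assert abs(r2(y, yhat) - (1 - sse / sst)) < 1e-12
            k = 3
            expect = 1 - (1 - (1 - sse / sst)) * (n - 1) / (n - k - 1)
            assert abs(adjusted_r2(y, yhat, k) - expect) < 1e-12

    def test_adjustment_never_exceeds_r2(self, rng):
        for _ in range(1000):
            n = int(rng.integers(6, 40))
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            k = int(rng.integers(1, n - 2))
            if r2(y, yhat) < 1.0:
                assert adjusted_r2(y, yhat, k) <= r2(y, yhat) + 1e-12

    def test_degenerate_inputs(self):
        assert np.isnan(r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            adjusted_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], k=2)


class TestRegressionTree:
    def test_separable_step_function_fits_perfectly(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        tree = RegressionTree(max_depth=1, min_samples_leaf=1).fit(X, y)
        assert mse(y, tree.predict(X)) == 0.0

    def test_depth1_split_matches_exhaustive_scan_oracle(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        y = X[:, 1] ** 2 + rng.normal(scale=0.3, size=n)
        tree = RegressionTree(max_depth=1, min_samples_leaf=1).fit(X, y)
        root = tree.root_

        def sse_after(feature, thr):
            left, right = y[X[:, feature] <= thr], y[X[:, feature] > thr]
            return (np.sum((left - left.mean()) ** 2)
                    + np.sum((right - right.mean()) ** 2))

        best = np.inf
        for f in range(3):
            xs = np.unique(X[:, f])
            for thr in (xs[1:] + xs[:-1]) / 2:
                best = min(best, sse_after(f, thr))
        assert np.isclose(sse_after(root.feature, root.threshold), best)

    def test_every_split_decreases_impurity(self, rng):
        X = rng.normal(size=(150, 4))
        y = X @ np.array([1.0, -2.0, 0.0, 0.5]) + rng.normal(size=150)
        tree = RegressionTree(min_samples_leaf=5).fit(X, y)
        for node in tree.iter_nodes():
            if not node.is_leaf:
                child_imp = node.left.impurity + node.right.impurity
                assert child_imp < node.impurity
                assert (node.left.n_samples + node.right.n_samples
                        == node.n_samples)

    def test_sklearn_agrees_on_depth1_split(self, rng):
        sklearn_tree = pytest.importorskip(
            "sklearn.tree").DecisionTreeRegressor
        X = rng.normal(size=(120, 2))
        y = np.where(X[:, 0] > 0.3, 2.0, -1.0) + rng.normal(scale=0.1,
                                                            size=120)
        ours = RegressionTree(max_depth=1, min_samples_leaf=1).fit(X, y)
        ref = sklearn_tree(max_depth=1).fit(X, y)
        assert ours.root_.feature == ref.tree_.feature[0]
        assert np.isclose(ours.root_.threshold, ref.tree_.threshold[0],
                          rtol=1e-9)


class TestForestAndImportance:
    def _planted(self, rng, n=300, p=5):
        X = rng.normal(size=(n, p))
        y = 3.0 * X[:, 0] + rng.normal(scale=0.5, size=n)
        return X, y

    def test_impurity_bookkeeping_identity(self, rng):
        X, y = self._planted(rng)
        forest = VarianceImpurityForest(
            ForestConfig(n_trees=5, seed=3)).fit(X, y)
        for tree in forest.trees_:
            leaf_imp = sum(nd.impurity for nd in tree.iter_nodes()
                           if nd.is_leaf)
            assert np.isclose(tree.importances_.sum(),
                              tree.root_.impurity - leaf_imp, rtol=1e-9)

    def test_single_split_tree_importance_share_is_one(self):
        X = np.array([[-1.0, 5.0], [-1.0, 5.0], [1.0, 5.0], [1.0, 5.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        forest = VarianceImpurityForest(ForestConfig(
            n_trees=1, bootstrap=False, min_samples_leaf=1, seed=0))
        forest.fit(X, y)
        imp = mdg_importance(forest, ["x0", "x1"])
        assert imp.share["x0"] == 1.0
        assert imp.share["x1"] == 0.0

    def test_shares_sum_to_one(self, rng):
        X, y = self._planted(rng)
        forest = VarianceImpurityForest(
            ForestConfig(n_trees=10, seed=1)).fit(X, y)
        imp = mdg_importance(forest)
        assert imp.any_split
        assert np.isclose(imp.share.sum(), 1.0)
        assert (imp.raw_mdg >= 0).all()

    def test_constant_response_warns_with_zero_importance(self):
        X = np.arange(20, dtype=float).reshape(-1, 1)
        y = np.full(20, 7.0)
        with pytest.warns(UserWarning, match="constant"):
            forest = VarianceImpurityForest(
                ForestConfig(n_trees=3, seed=0)).fit(X, y)
        np.testing.assert_allclose(forest.predict(X), 7.0)
        imp = mdg_importance(forest)
        assert not imp.any_split
        assert imp.share.isna().all()

    def test_reproducible_under_seed(self, rng):
        X, y = self._planted(rng)
        a = VarianceImpurityForest(ForestConfig(n_trees=8, seed=5)).fit(X, y)
        b = VarianceImpurityForest(ForestConfig(n_trees=8, seed=5)).fit(X, y)
        np.testing.assert_array_equal(a.predict(X[:20]), b.predict(X[:20]))

    def test_planted_signal_dominates_noise_features(self, rng):
        X, y = self._planted(rng, n=500, p=8)
        forest = VarianceImpurityForest(
            ForestConfig(n_trees=30, seed=2)).fit(X, y)
        share = mdg_importance(forest).share
        assert share.iloc[0] > 0.5
        assert share.iloc[1:].sum() < 0.5  # pure-noise attrs suppressed

    def test_direction_agrees_with_sklearn_forest(self, rng):
        ensemble = pytest.importorskip("sklearn.ensemble")
        X, y = self._planted(rng, n=400, p=4)
        ours = mdg_importance(VarianceImpurityForest(
            ForestConfig(n_trees=30, seed=4)).fit(X, y)).share
        ref = ensemble.RandomForestRegressor(
            n_estimators=30, random_state=4).fit(X, y).feature_importances_
        assert ours.idxmax() == f"x{np.argmax(ref)}"
        np.testing.assert_allclose(ours.to_numpy(), ref, atol=0.1)


class TestGWR:
    def _linear_data(self, rng, n=80):
        coords = rng.uniform(0, 10, size=(n, 2))
        X = rng.normal(size=(n, 2))
        y = 1.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
        return X, y, coords

    def test_infinite_bandwidth_limit_equals_global_ols(self, rng):
        X, y, coords = self._linear_data(rng)
        y = y + rng.normal(scale=0.3, size=len(y))
        gwr = GWR(bandwidth=1e6).fit(X, y, coords)
        A = np.column_stack([np.ones(len(y)), X])
        beta_ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        for i in range(len(y)):
            np.testing.assert_allclose(gwr.coef_[i], beta_ols, atol=1e-6)

    def test_noiseless_linear_surface_is_exact(self, rng):
        X, y, coords = self._linear_data(rng)
        gwr = GWR(bandwidth=3.0).fit(X, y, coords)
        assert r2(y, gwr.fitted_) > 1 - 1e-9

    def test_planted_coefficient_flip_beats_global_ols(self, rng):
        n = 120
        coords = np.column_stack([rng.uniform(0, 10, n),
                                  rng.uniform(0, 10, n)])
        X = rng.normal(size=(n, 1))
        slope = np.where(coords[:, 0] < 5, 2.0, -2.0)  # west/east flip
        y = slope * X[:, 0] + rng.normal(scale=0.2, size=n)
        gwr = GWR(bandwidth=1.5).fit(X, y, coords)
        A = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert mse(y, gwr.fitted_) < mse(y, A @ beta)

    def test_vanishing_bandwidth_rejected_with_guidance(self, rng):
        X, y, coords = self._linear_data(rng)
        with pytest.raises(ValueError, match="bandwidth"):
            GWR(bandwidth=1e-9).fit(X, y, coords)

    def test_bandwidth_selection_runs_and_is_positive(self, rng):
        X, y, coords = self._linear_data(rng, n=40)
        y = y + rng.normal(scale=0.2, size=40)
        gwr = GWR().fit(X, y, coords)
        assert gwr.bandwidth_ > 0


class TestCompareModels:
    def _datasets(self, rng):
        out = {}
        for land_use in ("working", "mixed"):
            n = 120
            coords = rng.uniform(0, 50, size=(n, 2))
            X = pd.DataFrame(rng.normal(size=(n, 3)),
                             columns=["gdp", "pop", "junctions"])
            y = -20 + 5 * X["gdp"].to_numpy() + rng.normal(scale=1, size=n)
            for period in ("period1",):
                out[(land_use, period)] = (X, y, coords)
        out[("residential", "period1")] = None
        return out

    def test_metrics_match_direct_calls_on_stored_predictions(self, rng):
        datasets = self._datasets(rng)
        comp, _ = compare_models(datasets,
                                 ForestConfig(n_trees=10, seed=1),
                                 bandwidth=20.0, seed=1)
        preds = comp.attrs["predictions"]
        for _, row in comp.iterrows():
            key = (row["land_use"], row["period"])
            if key not in preds:
                continue
            p = preds[key]
            assert np.isclose(row["mse_rf"], mse(p["y_train"],
                                                 p["rf_train"]))
            assert np.isclose(row["adj_r2_gwr"],
                              adjusted_r2(p["y_train"], p["gwr_train"],
                                          p["k"]))

    def test_missing_combination_reported_absent(self, rng):
        comp, _ = compare_models(self._datasets(rng),
                                 ForestConfig(n_trees=5, seed=0),
                                 bandwidth=20.0)
        row = comp[comp["land_use"] == "residential"].iloc[0]
        assert row["n"] == 0 and np.isnan(row["mse_rf"])

    def test_importance_shares_normalized_per_dataset(self, rng):
        _, imp = compare_models(self._datasets(rng),
                                ForestConfig(n_trees=5, seed=0),
                                bandwidth=20.0)
        sums = imp.groupby(["land_use", "period"])["share"].sum()
        np.testing.assert_allclose(sums, 1.0)
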