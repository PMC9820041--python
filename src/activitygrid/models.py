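"""Attribute-importance models: variance-impurity regression forest with
mean-decrease-Gini (MDG) importance, geographically weighted regression,
and the fit metrics used to compare them.

The forest is a bagged ensemble of CART regression trees grown greedily:
at every node the (variable, threshold) pair maximizing the decrease in
node impurity is chosen, where impurity is the total sum of squared
deviations from the node mean (the regression analog of Gini impurity).
A variable's MDG importance is the sum, over every split it forms in the
forest, of the parent impurity minus the children's impurities, divided
by the number of trees; importances are reported as normalized shares.

Written from first principles so that the impurity bookkeeping is fully
inspectable; scikit-learn is used only as an independent cross-check in
the test suite, never here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Train / test / validation split

def split_data(n: int, fractions=(0.55, 0.30, 0.15), seed: int = 0):
    """Random disjoint, exhaustive train/test/validation index partition.

    Test and validation sizes are the rounded fractions of ``n``; the
    remainder goes to train, so ``n=100`` gives sizes (55, 30, 15).
    """
    if n < 3:
        raise ValueError("need at least 3 observations to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    n_test = round(n * fractions[1])
    n_val = round(n * fractions[2])
    n_train = n - n_test - n_val
    if min(n_train, n_test, n_val) < 1:
        raise ValueError(f"n={n} too small to populate all three sets")
    perm = np.random.default_rng(seed).permutation(n)
    return (np.sort(perm[:n_train]),
            np.sort(perm[n_train:n_train + n_test]),
            np.sort(perm[n_train + n_test:]))


# ---------------------------------------------------------------------------
# CART regression tree

@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 100
    max_depth: int | None = None
    min_samples_leaf: int = 5
    features_per_split: int | str = "all"
    bootstrap: bool = True
    seed: int = 0
    split_fractions: tuple = (0.55, 0.30, 0.15)

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "value",
                 "n_samples", "impurity")

    def __init__(self, value, n_samples, impurity):
        self.feature = -1       # -1 marks a leaf
        self.threshold = np.nan
        self.left = None
        self.right = None
        self.value = value      # node mean = leaf prediction
        self.n_samples = n_samples
        self.impurity = impurity  # sum of squared deviations from value

    @property
    def is_leaf(self):
        return self.feature < 0


def _best_split(X, y, idx, feature_ids, min_leaf):
    """Exhaustive scan for the impurity-maximally-decreasing split.

    Candidate thresholds are midpoints between consecutive sorted unique
    feature values; ties in impurity decrease are broken by (lowest
    feature index, lowest threshold) for determinism.

    Returns (decrease, feature, threshold) or None if no valid split.
    """
    ysub = y[idx]
    n = len(ysub)
    tot = ysub.sum()
    parent_imp = np.sum(ysub * ysub) - tot * tot / n
    best = None
    for f in sorted(feature_ids):
        xs = X[idx, f]
        order = np.argsort(xs, kind="stable")
        xo = xs[order]
        yo = ysub[order]
        # split after position i (1-based count on the left)
        csum = np.cumsum(yo)
        cnt = np.arange(1, n + 1)
        # valid split points: between distinct x values, both sides >= min_leaf
        distinct = xo[1:] != xo[:-1]
        lo = cnt[:-1]
        valid = distinct & (lo >= min_leaf) & (n - lo >= min_leaf)
        if not valid.any():
            continue
        lsum = csum[:-1][valid]
        lcnt = lo[valid]
        rcnt = n - lcnt
        rsum = tot - lsum
        # decrease = parent SSE - (left SSE + right SSE)
        #          = lsum^2/lcnt + rsum^2/rcnt - tot^2/n
        dec = lsum * lsum / lcnt + rsum * rsum / rcnt - tot * tot / n
        j = int(np.argmax(dec))
        d = float(dec[j])
        if d <= 1e-12 * max(parent_imp, 1.0):
            continue
        pos = np.flatnonzero(valid)[j]
        thr = 0.5 * (xo[pos] + xo[pos + 1])
        if best is None or d > best[0] + 1e-12:
            best = (d, f, float(thr))
    return best


class RegressionTree:
    """A single CART regression tree with variance impurity.

    Leaves predict node means; every internal node strictly decreases
    the summed impurity.  Per-feature impurity decreases accumulate into
    ``importances_`` (unnormalized).
    """

    def __init__(self, max_depth=None, min_samples_leaf=5,
                 features_per_split="all", rng=None):
        self.max_depth = np.inf if max_depth is None else max_depth
        self.min_samples_leaf = min_samples_leaf
        self.features_per_split = features_per_split
        self.rng = rng or np.random.default_rng()
        self.root_ = None
        self.importances_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        self.importances_ = np.zeros(p)
        k = p if self.features_per_split == "all" else \
            min(int(self.features_per_split), p)
        self.root_ = self._grow(X, y, np.arange(n), depth=0, k=k, p=p)
        return self

    def _node_stats(self, y, idx):
        ysub = y[idx]
        mean = float(ysub.mean())
        imp = float(np.sum((ysub - mean) ** 2))
        return mean, imp

    def _grow(self, X, y, idx, depth, k, p):
        mean, imp = self._node_stats(y, idx)
        node = _Node(mean, len(idx), imp)
        if (depth >= self.max_depth or len(idx) < 2 * self.min_samples_leaf
                or imp <= 0):
            return node
        feats = (range(p) if k == p
                 else self.rng.choice(p, size=k, replace=False))
        best = _best_split(X, y, idx, feats, self.min_samples_leaf)
        if best is None:
            return node
        dec, f, thr = best
        node.feature = f
        node.threshold = thr
        self.importances_[f] += dec
        left = idx[X[idx, f] <= thr]
        right = idx[X[idx, f] > thr]
        node.left = self._grow(X, y, left, depth + 1, k, p)
        node.right = self._grow(X, y, right, depth + 1, k, p)
        return node

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root_
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold \
                    else node.right
            out[i] = node.value
        return out

    def iter_nodes(self):
        stack = [self.root_]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.extend((node.left, node.right))


class VarianceImpurityForest:
    """Bagged ensemble of CART regression trees.

    Predictions average the trees; variable importance is the MDG —
    the per-variable sum of impurity decreases over all splits in the
    forest, normalized by the number of trees.
    """

    def __init__(self, config: ForestConfig | None = None, **overrides):
        cfg = config or ForestConfig()
        if overrides:
            cfg = ForestConfig(**{**cfg.__dict__, **overrides})
        self.config = cfg
        self.trees_ = []
        self.n_features_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values are not supported")
        n, self.n_features_ = X.shape
        if np.unique(y).size == 1:
            warnings.warn("constant response: forest degenerates to stumps "
                          "with zero importances", stacklevel=2)
        rng = np.random.default_rng(self.config.seed)
        self.trees_ = []
        for _ in range(self.config.n_trees):
            tree_rng = np.random.default_rng(rng.integers(2**31))
            idx = (tree_rng.integers(0, n, size=n) if self.config.bootstrap
                   else np.arange(n))
            tree = RegressionTree(
                max_depth=self.config.max_depth,
                min_samples_leaf=self.config.min_samples_leaf,
                features_per_split=self.config.features_per_split,
                rng=tree_rng,
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict(self, X):
        preds = np.stack([t.predict(X) for t in self.trees_])
        return preds.mean(axis=0)


@dataclass
class ImportanceResult:
    """Raw MDG per attribute, normalized shares, and whether any split
    occurred (shares are undefined otherwise)."""

    raw_mdg: pd.Series
    share: pd.Series
    any_split: bool


def mdg_importance(forest: VarianceImpurityForest,
                   feature_names=None) -> ImportanceResult:
    """Mean-decrease-Gini importance of a fitted forest.

    raw MDG = (sum of impurity decreases over the variable's splits in
    all trees) / n_trees; shares normalize raw MDG to sum to 1.
    """
    if not forest.trees_:
        raise ValueError("forest is not fitted")
    raw = sum(t.importances_ for t in forest.trees_) / len(forest.trees_)
    names = (list(feature_names) if feature_names is not None
             else [f"x{i}" for i in range(forest.n_features_)])
    raw = pd.Series(raw, index=names, name="raw_mdg")
    total = raw.sum()
    any_split = total > 0
    if not any_split:
        logger.warning("forest contains no splits; importance shares "
                       "undefined")
    share = raw / total if any_split else raw * np.nan
    share.name = "share"
    return ImportanceResult(raw_mdg=raw, share=share, any_split=any_split)


# ---------------------------------------------------------------------------
# Fit metrics

def mse(y, y_hat) -> float:
    """Mean squared error (1/n) * sum (y - y_hat)^2."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def r2(y, y_hat) -> float:
    """Coefficient of determination 1 - SSE/SST; NaN when y is constant."""
    y, y_hat = _check_pair(y, y_hat)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        logger.warning("zero total variance: R^2 undefined")
        return np.nan
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / sst


def adjusted_r2(y, y_hat, k: int) -> float:
    """R^2 penalized for the number of covariates k:
    1 - (1 - R^2)(n - 1)/(n - k - 1)."""
    y, y_hat = _check_pair(y, y_hat)
    n = len(y)
    if n - k - 1 <= 0:
        raise ValueError(f"adjusted R^2 requires n - k - 1 > 0 "
                         f"(n={n}, k={k})")
    r = r2(y, y_hat)
    return 1.0 - (1.0 - r) * (n - 1) / (n - k - 1)


def _check_pair(y, y_hat):
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be 1-D of equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    return y, y_hat


# ---------------------------------------------------------------------------
# Geographically weighted regression

class GWR:
    """Geographically weighted regression with a Gaussian kernel.

    At each calibration location a weighted least-squares fit is solved
    with observation weights exp(-d^2 / (2 * bandwidth^2)); predictions
    at a location use its local coefficients, so coefficients vary
    smoothly in space.  Singular local systems are resolved by a small
    ridge jitter (logged).  ``bandwidth=None`` selects it by
    leave-one-out CV over a logarithmic grid of pairwise-distance
    quantiles.
    """

    def __init__(self, bandwidth: float | None = None, ridge: float = 1e-8):
        if bandwidth is not None and bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.bandwidth = bandwidth
        self.ridge = ridge
        self.coef_ = None        # (n, p+1), intercept first
        self.fitted_ = None
        self.coords_ = None
        self.bandwidth_ = None

    @staticmethod
    def _design(X):
        X = np.asarray(X, dtype=float)
        return np.column_stack([np.ones(len(X)), X])

    def _local_fit(self, A, y, w):
        AW = A * w[:, None]
        G = A.T @ AW
        b = AW.T @ y
        try:
            return np.linalg.solve(G, b), False
        except np.linalg.LinAlgError:
            p = G.shape[0]
            return np.linalg.solve(G + self.ridge * np.trace(G) / p
                                   * np.eye(p), b), True

    def fit(self, X, y, coords):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        coords = np.asarray(coords, dtype=float)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError("need n > p + 1 observations")
        bw = self.bandwidth
        if bw is None:
            bw = self._select_bandwidth(X, y, coords)
        A = self._design(X)
        d2 = self._sq_dists(coords, coords)
        self.coef_ = np.empty((n, p + 1))
        n_jitter = 0
        for i in range(n):
            w = np.exp(-d2[i] / (2 * bw * bw))
            if (w > 1e-10).sum() < p + 1:
                raise ValueError(
                    f"bandwidth {bw:g} leaves location {i} with fewer than "
                    f"p+1={p+1} effectively weighted neighbours; increase "
                    "the bandwidth")
            beta, jittered = self._local_fit(A, y, w)
            n_jitter += jittered
            self.coef_[i] = beta
        if n_jitter:
            logger.info("ridge jitter applied at %d locations", n_jitter)
        self.fitted_ = np.sum(A * self.coef_, axis=1)
        self.coords_ = coords
        self.bandwidth_ = bw
        return self

    @staticmethod
    def _sq_dists(a, b):
        diff = a[:, None, :] - b[None, :, :]
        return np.sum(diff * diff, axis=-1)

    def _select_bandwidth(self, X, y, coords, n_grid: int = 8):
        """Leave-one-out CV on a log grid of pairwise-distance scales."""
        d2 = self._sq_dists(coords, coords)
        d = np.sqrt(d2[np.triu_indices(len(coords), k=1)])
        d = d[d > 0]
        grid = np.exp(np.linspace(np.log(np.quantile(d, 0.05)),
                                  np.log(d.max()), n_grid))
        A = self._design(X)
        p1 = A.shape[1]
        best_bw, best_err = grid[-1], np.inf
        for bw in grid:
            W = np.exp(-d2 / (2 * bw * bw))
            np.fill_diagonal(W, 0.0)  # leave-one-out
            errs = []
            ok = True
            for i in range(len(y)):
                if (W[i] > 1e-10).sum() < p1:
                    ok = False
                    break
                beta, _ = self._local_fit(A, y, W[i])
                errs.append((y[i] - A[i] @ beta) ** 2)
            if ok:
                err = float(np.mean(errs))
                if err < best_err:
                    best_err, best_bw = err, bw
        logger.info("GWR bandwidth selected by LOO CV: %g", best_bw)
        return float(best_bw)

    def predict(self, X, coords):
        """Predict at new locations using the nearest calibration
        location's coefficients."""
        if self.coef_ is None:
            raise ValueError("GWR is not fitted")
        A = self._design(X)
        d2 = self._sq_dists(np.asarray(coords, dtype=float), self.coords_)
        nearest = d2.argmin(axis=1)
        return np.sum(A * self.coef_[nearest], axis=1)


# ---------------------------------------------------------------------------
# Model comparison

def compare_models(datasets: dict, forest_config: ForestConfig | None = None,
                   bandwidth: float | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Fit the forest and GWR per (land-use class x period) dataset and
    tabulate MSE and adjusted R^2 for both on identical splits.

    Parameters
    ----------
    datasets : mapping ``(land_use, period) -> (X, y, coords)`` where X
        is an (n, p) attribute DataFrame or array, y the change rates,
        coords the (n, 2) cell centroids.

    Returns
    -------
    comparison : tidy DataFrame, one row per (land_use, period): MSE
        and adjusted R^2 for GWR and for the forest on the training
        partition (test-partition MSEs echoed).  Missing combinations
        appear as rows with NaN metrics.
    importances : tidy DataFrame (land_use, period, attribute,
        raw_mdg, share) from the forest fitted on the training
        partition.
    """
    cfg = forest_config or ForestConfig(seed=seed)
    rows = []
    imp_rows = []
    predictions = {}
    for (land_use, period), data in datasets.items():
        if data is None:
            rows.append({"land_use": land_use, "period": period,
                         "n": 0, "mse_gwr": np.nan, "mse_rf": np.nan,
                         "adj_r2_gwr": np.nan, "adj_r2_rf": np.nan,
                         "mse_gwr_test": np.nan, "mse_rf_test": np.nan})
            continue
        X, y, coords = data
        names = (list(X.columns) if isinstance(X, pd.DataFrame)
                 else [f"x{i}" for i in range(np.asarray(X).shape[1])])
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        coords = np.asarray(coords, dtype=float)
        k = X.shape[1]
        tr, te, va = split_data(len(y), cfg.split_fractions, seed=seed)

        forest = VarianceImpurityForest(cfg).fit(X[tr], y[tr])
        gwr = GWR(bandwidth=bandwidth).fit(X[tr], y[tr], coords[tr])

        yhat_rf_tr = forest.predict(X[tr])
        yhat_gwr_tr = gwr.fitted_
        yhat_rf_te = forest.predict(X[te])
        yhat_gwr_te = gwr.predict(X[te], coords[te])

        rows.append({
            "land_use": land_use, "period": period, "n": len(y),
            "mse_gwr": mse(y[tr], yhat_gwr_tr),
            "mse_rf": mse(y[tr], yhat_rf_tr),
            "adj_r2_gwr": adjusted_r2(y[tr], yhat_gwr_tr, k),
            "adj_r2_rf": adjusted_r2(y[tr], yhat_rf_tr, k),
            "mse_gwr_test": mse(y[te], yhat_gwr_te),
            "mse_rf_test": mse(y[te], yhat_rf_te),
        })
        imp = mdg_importance(forest, names)
        for attr in names:
            imp_rows.append({"land_use": land_use, "period": period,
                             "attribute": attr,
                             "raw_mdg": imp.raw_mdg[attr],
                             "share": imp.share[attr]})
        predictions[(land_use, period)] = {
            "y_train": y[tr], "rf_train": yhat_rf_tr,
            "gwr_train": yhat_gwr_tr, "y_test": y[te],
            "rf_test": yhat_rf_te, "gwr_test": yhat_gwr_te, "k": k,
        }
    comparison = pd.DataFrame(rows)
    comparison.attrs["predictions"] = predictions
    return comparison, pd.DataFrame(imp_rows)
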