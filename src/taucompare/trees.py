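"""Regression trees, bagging and variable importance.

Binary recursive partitioning: each internal node splits one predictor at a
threshold chosen by exhaustive search to minimize the summed within-child
squared error; leaves predict their training mean. Trees are pruned by
cost-complexity (weakest-link) collapsing with the complexity parameter
chosen by k-fold cross-validation, then aggregated over bootstrap resamples
(bagging). The variable importance measure (VIM) of a predictor is its
summed squared-error decrease over all splits, averaged over the bagged
trees and divided by the full-sample root squared error about the mean — a
dimensionless, reproducible convention; only ranks and relative magnitudes
are comparable across VIM conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .impute import ImputedSet


@dataclass
class TreeNode:
    n: int
    sse: float
    prediction: float
    feature: int | None = None
    threshold: float | None = None
    gain: float = 0.0  # SSE decrease achieved by this node's split
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    root: TreeNode
    feature_names: list[str]
    min_node: int
    min_decrease_frac: float
    #: complexity parameter the tree was pruned at (None if unpruned)
    complexity: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out

    def internal_nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend([node.left, node.right])
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())

    def to_dict(self) -> dict:
        def rec(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"n": node.n, "prediction": node.prediction, "sse": node.sse}
            return {
                "n": node.n, "sse": node.sse, "gain": node.gain,
                "feature": self.feature_names[node.feature],
                "threshold": node.threshold,
                "left": rec(node.left), "right": rec(node.right),
            }
        return rec(self.root)


def _node_sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if len(y) else 0.0


def _best_split(X: np.ndarray, y: np.ndarray, min_node: int) -> tuple[int, float, float] | None:
    """Exhaustive search over (feature, midpoint) splits maximizing SSE decrease.

    Ties go to the lower feature index, then the lower threshold. Returns
    (feature, threshold, gain) or None when no admissible split exists.
    """
    n, p = X.shape
    total = y.sum()
    parent_fit = total * total / n
    best: tuple[int, float, float] | None = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        cum = np.cumsum(ys)
        n_left = np.arange(1, n)
        # admissible boundaries: between distinct values, children >= min_node
        distinct = xs[1:] != xs[:-1]
        ok = distinct & (n_left >= min_node) & ((n - n_left) >= min_node)
        if not ok.any():
            continue
        left_sum = cum[:-1]
        fit = left_sum**2 / n_left + (total - left_sum) ** 2 / (n - n_left)
        fit[~ok] = -np.inf
        i = int(np.argmax(fit))  # argmax takes the first max: lowest threshold
        gain = float(fit[i] - parent_fit)
        if gain <= 0:
            continue
        thr = float((xs[i] + xs[i + 1]) / 2.0)
        if best is None or gain > best[2] + 1e-12:
            best = (j, thr, gain)
    return best


def grow_tree(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str] | None = None,
              min_node: int = 20, min_decrease_frac: float = 0.01) -> RegressionTree:
    """Grow a regression tree by greedy binary recursive partitioning.

    Splitting stops when a node holds fewer than ``2 * min_node`` rows or
    when the best split's SSE decrease falls below ``min_decrease_frac``
    of the root SSE. A constant outcome yields a single leaf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per outcome value")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    root_sse = _node_sse(y)
    min_gain = min_decrease_frac * root_sse

    def build(idx: np.ndarray) -> TreeNode:
        yi = y[idx]
        node = TreeNode(n=len(idx), sse=_node_sse(yi), prediction=float(yi.mean()))
        if len(idx) < 2 * min_node or node.sse <= 0:
            return node
        found = _best_split(X[idx], yi, min_node)
        if found is None:
            return node
        j, thr, gain = found
        if gain < min_gain:
            return node
        node.feature, node.threshold, node.gain = j, thr, gain
        mask = X[idx, j] <= thr
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    return RegressionTree(root=build(np.arange(len(y))), feature_names=list(feature_names),
                          min_node=min_node, min_decrease_frac=min_decrease_frac)


def _subtree_stats(node: TreeNode) -> tuple[float, int]:
    """(summed leaf SSE, leaf count) of the subtree rooted at ``node``."""
    if node.is_leaf:
        return node.sse, 1
    ls, ln = _subtree_stats(node.left)
    rs, rn = _subtree_stats(node.right)
    return ls + rs, ln + rn


def _prune_inplace(tree: RegressionTree, alpha: float) -> None:
    """Collapse weakest links until every remaining link is worth more than alpha."""
    while True:
        weakest, weakest_g = None, np.inf
        for node in tree.internal_nodes():
            sub_sse, sub_leaves = _subtree_stats(node)
            g = (node.sse - sub_sse) / (sub_leaves - 1)
            if g < weakest_g - 1e-12:
                weakest, weakest_g = node, g
        if weakest is None or weakest_g > alpha:
            break
        weakest.feature = weakest.threshold = None
        weakest.left = weakest.right = None
        weakest.gain = 0.0
    tree.complexity = alpha


def _prune_at(tree: RegressionTree, alpha: float) -> RegressionTree:
    import copy

    pruned = copy.deepcopy(tree)
    _prune_inplace(pruned, alpha)
    return pruned


def _alpha_sequence(tree: RegressionTree) -> list[float]:
    """Critical complexity values of the weakest-link pruning path."""
    import copy

    work = copy.deepcopy(tree)
    alphas = [0.0]
    while not work.root.is_leaf:
        weakest, weakest_g = None, np.inf
        for node in work.internal_nodes():
            sub_sse, sub_leaves = _subtree_stats(node)
            g = (node.sse - sub_sse) / (sub_leaves - 1)
            if g < weakest_g - 1e-12:
                weakest, weakest_g = node, g
        alphas.append(weakest_g)
        # collapse every node at this critical value
        for node in work.internal_nodes():
            sub_sse, sub_leaves = _subtree_stats(node)
            if (node.sse - sub_sse) / (sub_leaves - 1) <= weakest_g + 1e-12:
                node.feature = node.threshold = None
                node.left = node.right = None
    return alphas


def prune_tree(tree: RegressionTree, X: np.ndarray, y: np.ndarray,
               k_folds: int = 10, seed: int = 0, one_se: bool = True) -> RegressionTree:
    """Cost-complexity pruning with the penalty chosen by k-fold cross-validation.

    Candidate penalties are geometric means of consecutive critical values of
    the master tree's pruning path. With ``one_se`` (default) the largest
    penalty whose cross-validated error lies within one standard error of the
    minimum wins — the standard CART operationalization of "ties go to the
    smaller tree"; otherwise the exact minimizer wins with ties resolved
    toward the larger penalty. An already-single-leaf tree is returned
    unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if tree.root.is_leaf:
        return tree
    n = len(y)
    if n < k_folds:
        raise ValueError(f"n={n} smaller than k_folds={k_folds}")
    alphas = _alpha_sequence(tree)
    candidates = [0.0]
    for a, b in zip(alphas[:-1], alphas[1:]):
        candidates.append(float(np.sqrt(max(a, 1e-30) * max(b, 1e-30))))
    candidates.append(alphas[-1] * 1.001 + 1e-30)
    candidates = sorted(set(candidates))

    rng = np.random.default_rng([seed, 5])
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    fold_mse = np.zeros((len(folds), len(candidates)))
    for fi, fold in enumerate(folds):
        test = np.zeros(n, dtype=bool)
        test[fold] = True
        sub = grow_tree(X[~test], y[~test], tree.feature_names,
                        min_node=tree.min_node, min_decrease_frac=tree.min_decrease_frac)
        # candidates are ascending, so pruning can proceed on one working copy
        for ci, alpha in enumerate(candidates):
            _prune_inplace(sub, alpha)
            pred = sub.predict(X[test])
            fold_mse[fi, ci] = float(np.mean((y[test] - pred) ** 2))
    mean = fold_mse.mean(axis=0)
    best = int(np.argmin(mean))
    if one_se:
        se = float(fold_mse[:, best].std(ddof=1) / np.sqrt(len(folds)))
        threshold = mean[best] + se
    else:
        threshold = mean[best] * (1 + 1e-12)
    alpha_star = max(a for ci, a in enumerate(candidates) if mean[ci] <= threshold)
    return _prune_at(tree, alpha_star)


@dataclass
class BaggedEnsemble:
    trees: list[RegressionTree]
    oob_indices: list[np.ndarray]
    feature_names: list[str]
    root_sse: float  # full-sample SSE about the mean, VIM normalizer

    @property
    def B(self) -> int:
        return len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.mean([t.predict(X) for t in self.trees], axis=0)


def bag(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str] | None = None,
        B: int = 25, seed: int = 0, prune: bool = True, k_folds: int = 10,
        min_node: int = 20, min_decrease_frac: float = 0.01) -> BaggedEnsemble:
    """Bootstrap-aggregate grown (and by default pruned) regression trees."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng([seed, 6])
    n = len(y)
    trees, oob = [], []
    for b in range(B):
        idx = rng.integers(n, size=n)
        tree = grow_tree(X[idx], y[idx], feature_names,
                         min_node=min_node, min_decrease_frac=min_decrease_frac)
        if prune:
            tree = prune_tree(tree, X[idx], y[idx], k_folds=min(k_folds, n),
                              seed=seed * 1000 + b)
        trees.append(tree)
        oob.append(np.setdiff1d(np.arange(n), idx))
    return BaggedEnsemble(trees=trees, oob_indices=oob,
                          feature_names=list(feature_names), root_sse=_node_sse(y))


def variable_importance(ensemble: BaggedEnsemble) -> pd.Series:
    """Mean per-tree summed SSE decrease per predictor, scaled by the root SSE.

    A predictor never split on has importance exactly 0.
    """
    if ensemble.B == 0:
        raise ValueError("empty ensemble")
    p = len(ensemble.feature_names)
    totals = np.zeros(p)
    for tree in ensemble.trees:
        for node in tree.internal_nodes():
            totals[node.feature] += node.gain
    vim = totals / ensemble.B / max(ensemble.root_sse, 1e-30)
    return pd.Series(vim, index=ensemble.feature_names, name="vim")


def vim_across_imputations(imputed: ImputedSet, outcome: str,
                           predictors: Sequence[str], B: int = 25, seed: int = 0,
                           prune: bool = True, min_node: int = 20,
                           min_decrease_frac: float = 0.01,
                           rows: np.ndarray | None = None) -> pd.DataFrame:
    """One bagged ensemble per imputed table; VIM distribution per predictor.

    Returns a frame indexed by predictor with the per-imputation VIM columns
    ``vim_00..``, the median, the 2.5/97.5 percentiles and the median-based
    rank (1 = most important; ties broken alphabetically). ``rows`` optionally
    restricts to a stratum (boolean mask or positional indices).
    """
    if outcome not in imputed.tables[0].columns:
        raise KeyError(f"outcome column {outcome!r} missing")
    from .ridge import _encode  # shared numeric encoding (sex -> 0/1)

    per_imp = []
    for i, t in enumerate(imputed.tables):
        if rows is None:
            tt = t
        else:
            r = np.asarray(rows)
            tt = t[r] if r.dtype == bool else t.iloc[r]
        X = _encode(tt, predictors)
        y = _encode(tt, [outcome])[:, 0]
        ens = bag(X, y, predictors, B=B, seed=seed * 100 + i, prune=prune,
                  min_node=min_node, min_decrease_frac=min_decrease_frac)
        per_imp.append(variable_importance(ens))
    mat = pd.concat(per_imp, axis=1)
    mat.columns = [f"vim_{i:02d}" for i in range(len(per_imp))]
    out = mat.copy()
    out["median"] = mat.median(axis=1)
    out["lo"] = mat.quantile(0.025, axis=1)
    out["hi"] = mat.quantile(0.975, axis=1)
    order = sorted(out.index, key=lambda name: (-out.loc[name, "median"], name))
    out["rank"] = pd.Series({name: r + 1 for r, name in enumerate(order)})
    return out.sort_values("rank")
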