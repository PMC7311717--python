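"""From-scratch decision trees, weighted-feature random forests, iterative
random forests (iRF), decision-path extraction and random intersection
trees (RIT).

This is the package's inference engine and is deliberately self-contained:
CART-style trees with exact midpoint split search, Gini impurity for
classification and variance for regression; bootstrapped forests with
impurity-decrease feature importance; iRF reweights the per-node feature
sampling distribution by the previous iteration's importances so splits
concentrate on stable signal features; RIT intersects randomly sampled
root-to-leaf feature sets to find feature combinations that co-occur on
many decision paths; outer bootstrap bags score the stability of those
interactions.

All randomness flows from a single :class:`numpy.random.Generator`; each
tree receives an independent child stream via ``Generator.spawn``, so
results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ForestParams",
    "RITParams",
    "TreeNode",
    "Forest",
    "IRFModel",
    "FeaturePath",
    "Interaction",
    "fit_tree",
    "fit_forest",
    "fit_irf",
    "extract_paths",
    "random_intersection_trees",
    "stability_interactions",
    "IterativeRandomForest",
    "IRFResults",
]

TASKS = ("classification", "regression")


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters. ``mtry``/``min_leaf`` default per task:
    mtry = ceil(sqrt(p)) for classification, ceil(p/3) for regression;
    min_leaf = 1 / 5; depth unlimited unless capped."""

    n_trees: int = 500
    mtry: int | None = None
    min_leaf: int | None = None
    max_depth: int | None = None

    def resolve(self, n_features: int, task: str) -> "ForestParams":
        mtry = self.mtry
        if mtry is None:
            mtry = (
                int(np.ceil(np.sqrt(n_features)))
                if task == "classification"
                else int(np.ceil(n_features / 3))
            )
        if mtry > n_features:
            warnings.warn(
                f"mtry={mtry} exceeds n_features={n_features}; clamping", stacklevel=2
            )
            mtry = n_features
        min_leaf = self.min_leaf
        if min_leaf is None:
            min_leaf = 1 if task == "classification" else 5
        return replace(self, mtry=mtry, min_leaf=min_leaf)


@dataclass(frozen=True)
class RITParams:
    """Random-intersection-tree hyperparameters (literature defaults)."""

    n_rit_trees: int = 100
    depth: int = 5
    n_child: int = 2
    min_size: int = 2


@dataclass
class TreeNode:
    """A CART node; ``feature == -1`` marks a leaf."""

    n_samples: int
    impurity: float
    value: np.ndarray | float  # class-probability vector or mean response
    feature: int = -1
    threshold: float = float("nan")
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


def _gini(counts: np.ndarray, n: int) -> float:
    return 1.0 - float((counts.astype(float) ** 2).sum()) / (n * n)


def _node_value(y: np.ndarray, task: str, n_classes: int):
    if task == "classification":
        counts = np.bincount(y, minlength=n_classes)
        return counts / counts.sum()
    return float(y.mean())


def _node_impurity(y: np.ndarray, task: str, n_classes: int) -> float:
    if task == "classification":
        return _gini(np.bincount(y, minlength=n_classes), len(y))
    return float(np.var(y))


def _best_split_feature(x: np.ndarray, y: np.ndarray, task: str, n_classes: int,
                        min_leaf: int, parent_impurity: float):
    """Best (decrease, threshold) for one feature; None if no valid split.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; children must each keep >= min_leaf samples. The first
    (lowest-threshold) maximizer wins.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    valid = xs[:-1] < xs[1:]
    pos = np.arange(1, n)  # left child size at each boundary
    valid &= (pos >= min_leaf) & (n - pos >= min_leaf)
    if not valid.any():
        return None
    if task == "classification":
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), y[order]] = 1.0
        cum = np.cumsum(onehot, axis=0)[:-1]  # left counts at each boundary
        total = cum[-1] + onehot[-1]
        n_left = pos.astype(float)
        n_right = n - n_left
        gini_left = 1.0 - (cum**2).sum(axis=1) / n_left**2
        right = total[None, :] - cum
        gini_right = 1.0 - (right**2).sum(axis=1) / n_right**2
        child = (n_left * gini_left + n_right * gini_right) / n
    else:
        ys = y[order].astype(float)
        cy = np.cumsum(ys)[:-1]
        cy2 = np.cumsum(ys**2)[:-1]
        ty, ty2 = float(ys.sum()), float((ys**2).sum())
        n_left = pos.astype(float)
        n_right = n - n_left
        var_left = np.maximum(cy2 / n_left - (cy / n_left) ** 2, 0.0)
        var_right = np.maximum(
            (ty2 - cy2) / n_right - ((ty - cy) / n_right) ** 2, 0.0
        )
        child = (n_left * var_left + n_right * var_right) / n
    decrease = np.where(valid, parent_impurity - child, -np.inf)
    best = int(np.argmax(decrease))  # first max -> lowest threshold
    if decrease[best] <= 0:
        return None
    threshold = (xs[best] + xs[best + 1]) / 2.0
    return float(decrease[best]), float(threshold)


def _sample_features(weights: np.ndarray, mtry: int, rng: np.random.Generator) -> np.ndarray:
    nonzero = np.flatnonzero(weights > 0)
    k = min(mtry, len(nonzero))
    if k == len(nonzero):
        chosen = nonzero
    else:
        p = weights[nonzero] / weights[nonzero].sum()
        chosen = nonzero[rng.choice(len(nonzero), size=k, replace=False, p=p)]
    return np.sort(chosen)


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "classification",
    feature_weights: np.ndarray | None = None,
    params: ForestParams | None = None,
    rng: np.random.Generator | None = None,
    n_classes: int | None = None,
    importance_out: np.ndarray | None = None,
) -> TreeNode:
    """Grow one weighted-feature CART tree.

    At each node ``mtry`` features are sampled without replacement with
    probability proportional to ``feature_weights``; the (feature,
    midpoint) pair maximizing impurity decrease is chosen, ties broken by
    lowest feature index then lowest threshold. If ``importance_out`` is
    given, each split adds n_node * decrease to its feature's slot.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if task == "classification":
        y = y.astype(int)
        n_classes = n_classes or int(y.max()) + 1
    n, p = X.shape
    if n < 1:
        raise ValueError("need at least one sample")
    if feature_weights is None:
        feature_weights = np.ones(p)
    feature_weights = np.asarray(feature_weights, dtype=float)
    if (feature_weights < 0).any():
        raise ValueError("feature weights must be nonnegative")
    if feature_weights.sum() <= 0:
        raise ValueError("feature weights must not be all zero")
    params = (params or ForestParams()).resolve(p, task)
    rng = rng or np.random.default_rng()

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yi = y[idx]
        impurity = _node_impurity(yi, task, n_classes or 0)
        node = TreeNode(
            n_samples=len(idx),
            impurity=impurity,
            value=_node_value(yi, task, n_classes or 0),
        )
        if (
            impurity <= 1e-12
            or len(idx) < 2 * params.min_leaf
            or (params.max_depth is not None and depth >= params.max_depth)
        ):
            return node
        features = _sample_features(feature_weights, params.mtry, rng)
        best = None  # (decrease, feature, threshold)
        for f in features:
            res = _best_split_feature(
                X[idx, f], yi, task, n_classes or 0, params.min_leaf, impurity
            )
            if res is None:
                continue
            decrease, threshold = res
            if best is None or decrease > best[0]:
                best = (decrease, f, threshold)
        if best is None:
            return node
        decrease, f, threshold = best
        if importance_out is not None:
            importance_out[f] += len(idx) * decrease
        mask = X[idx, f] <= threshold
        node.feature = int(f)
        node.threshold = threshold
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(n), 0)


def _tree_apply(node: TreeNode, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] = node.value
        return
    mask = X[idx, node.feature] <= node.threshold
    _tree_apply(node.left, X, idx[mask], out)
    _tree_apply(node.right, X, idx[~mask], out)


def tree_predict(node: TreeNode, X: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Leaf values for each row: class-probability vectors or means."""
    X = np.asarray(X, dtype=float)
    if n_classes:
        out = np.zeros((len(X), n_classes))
    else:
        out = np.zeros(len(X))
    _tree_apply(node, X, np.arange(len(X)), out)
    return out


@dataclass
class Forest:
    """A fitted random forest with per-tree bootstrap bookkeeping."""

    trees: list[TreeNode]
    task: str
    params: ForestParams
    n_features: int
    n_classes: int | None
    bootstrap_indices: list[np.ndarray]
    importances_: np.ndarray  # normalized to sum 1 (or all zero)
    raw_importance_: np.ndarray = field(repr=False, default=None)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("predict_proba is classification-only")
        acc = np.zeros((len(X), self.n_classes))
        for tree in self.trees:
            acc += tree_predict(tree, X, self.n_classes)
        return acc / len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.task == "classification":
            return np.argmax(self.predict_proba(X), axis=1)
        acc = np.zeros(len(X))
        for tree in self.trees:
            acc += tree_predict(tree, X)
        return acc / len(self.trees)

    def oob_predict(self, X: np.ndarray) -> np.ndarray:
        """Out-of-bag prediction on the training matrix (NaN where a row
        was in-bag for every tree)."""
        n = len(X)
        if self.task == "classification":
            acc = np.zeros((n, self.n_classes))
        else:
            acc = np.zeros(n)
        counts = np.zeros(n)
        for tree, idx in zip(self.trees, self.bootstrap_indices):
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            if len(oob) == 0:
                continue
            pred = tree_predict(tree, X[oob], self.n_classes)
            acc[oob] += pred
            counts[oob] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.task == "classification":
                proba = acc / counts[:, None]
                out = np.where(counts > 0, np.argmax(np.nan_to_num(proba), axis=1), -1).astype(float)
                out[counts == 0] = np.nan
                return out
            out = acc / counts
        return out


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "classification",
    feature_weights: np.ndarray | None = None,
    params: ForestParams | None = None,
    rng: np.random.Generator | None = None,
) -> Forest:
    """Fit a bootstrapped forest; importance is impurity decrease weighted
    by node size, summed over nodes, averaged over trees, normalized to
    sum 1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if task == "classification":
        y = y.astype(int)
        n_classes = int(y.max()) + 1
    else:
        n_classes = None
    params = (params or ForestParams()).resolve(p, task)
    rng = rng or np.random.default_rng()
    child_rngs = rng.spawn(params.n_trees)

    trees: list[TreeNode] = []
    boots: list[np.ndarray] = []
    raw = np.zeros(p)
    for child in child_rngs:
        idx = child.integers(0, n, size=n)
        imp = np.zeros(p)
        tree = fit_tree(
            X[idx], y[idx], task=task, feature_weights=feature_weights,
            params=params, rng=child, n_classes=n_classes, importance_out=imp,
        )
        trees.append(tree)
        boots.append(idx)
        raw += imp
    raw /= params.n_trees
    total = raw.sum()
    importances = raw / total if total > 0 else raw.copy()
    return Forest(
        trees=trees, task=task, params=params, n_features=p, n_classes=n_classes,
        bootstrap_indices=boots, importances_=importances, raw_importance_=raw,
    )


@dataclass
class IRFModel:
    """Forests and feature-weight trajectory across iRF iterations."""

    forests: list[Forest]
    weights: list[np.ndarray]  # sampling weights per iteration, sum 1
    task: str

    @property
    def forest(self) -> Forest:
        """The final-iteration forest."""
        return self.forests[-1]

    @property
    def importances_(self) -> np.ndarray:
        """Final importance vector (sums to 1)."""
        return self.forest.importances_


def fit_irf(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "classification",
    n_iterations: int = 5,
    params: ForestParams | None = None,
    rng: np.random.Generator | None = None,
) -> IRFModel:
    """Iterative random forest: iteration 1 uses uniform feature-sampling
    weights; iteration t+1 samples features proportionally to iteration
    t's importance vector. An all-zero importance reverts to uniform
    weights with a warning."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    rng = rng or np.random.default_rng()
    w = np.full(p, 1.0 / p)
    forests, weights = [], []
    for _ in range(n_iterations):
        weights.append(w.copy())
        forest = fit_forest(X, y, task=task, feature_weights=w, params=params, rng=rng)
        forests.append(forest)
        imp = forest.importances_
        if imp.sum() <= 0:
            warnings.warn("all-zero importance; reverting to uniform weights", stacklevel=2)
            w = np.full(p, 1.0 / p)
        else:
            w = imp / imp.sum()
    return IRFModel(forests=forests, weights=weights, task=task)


@dataclass(frozen=True)
class FeaturePath:
    """The set of split features on one root-to-leaf path."""

    features: frozenset
    weight: float  # leaf n_samples
    label: int | None = None  # predicted class, classification only


def extract_paths(forest: Forest, class_filter: int | None = None) -> list[FeaturePath]:
    """One path per leaf (root-leaf trees contribute none), optionally
    restricted to leaves predicting ``class_filter``."""
    paths: list[FeaturePath] = []

    def walk(node: TreeNode, acc: set) -> None:
        if node.is_leaf:
            if not acc:
                return
            label = None
            if forest.task == "classification":
                label = int(np.argmax(node.value))
                if class_filter is not None and label != class_filter:
                    return
            paths.append(FeaturePath(frozenset(acc), float(node.n_samples), label))
            return
        acc = acc | {node.feature}
        walk(node.left, acc)
        walk(node.right, acc)

    for tree in forest.trees:
        walk(tree, set())
    return paths


def path_prevalence(paths: list[FeaturePath], feature_set: frozenset) -> float:
    """Leaf-weighted fraction of paths whose feature set contains S."""
    total = sum(p.weight for p in paths)
    if total == 0:
        return 0.0
    return sum(p.weight for p in paths if feature_set <= p.features) / total


def random_intersection_trees(
    paths: list[FeaturePath],
    rit: RITParams | None = None,
    rng: np.random.Generator | None = None,
) -> dict[frozenset, float]:
    """Run RIT over decision paths; returns {surviving set: prevalence}.

    Each RIT tree roots at a path set sampled with probability
    proportional to leaf weight; every node spawns ``n_child`` children,
    each intersecting the parent set with a freshly sampled path set.
    Sets of size >= ``min_size`` surviving at the target depth are
    candidates; prevalence is the leaf-weighted fraction of paths
    containing the set.
    """
    if not paths:
        raise ValueError("no decision paths to intersect")
    rit = rit or RITParams()
    rng = rng or np.random.default_rng()
    weights = np.array([p.weight for p in paths], dtype=float)
    probs = weights / weights.sum()
    survivors: set[frozenset] = set()

    def sample_set() -> frozenset:
        return paths[int(rng.choice(len(paths), p=probs))].features

    def expand(current: frozenset, depth: int) -> None:
        if len(current) < rit.min_size:
            return  # cannot recover below min_size by intersecting further
        if depth == rit.depth:
            survivors.add(current)
            return
        for _ in range(rit.n_child):
            expand(current & sample_set(), depth + 1)

    for _ in range(rit.n_rit_trees):
        expand(sample_set(), 0)
    return {s: path_prevalence(paths, s) for s in survivors}


@dataclass
class Interaction:
    """A candidate feature interaction with outer-bag stability."""

    features: frozenset
    prevalence: float  # mean prevalence over bags where it survived
    stability: float  # fraction of outer bags recovering the set


def stability_interactions(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "classification",
    n_iterations: int = 5,
    params: ForestParams | None = None,
    rit: RITParams | None = None,
    n_bags: int = 10,
    class_filter: int | None = None,
    min_prevalence: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[Interaction]:
    """Outer-bootstrap stability scoring of RIT interactions.

    For each of ``n_bags`` bootstrap resamples of the rows an iRF is fit
    and RIT run on its final forest; an interaction counts as recovered in
    a bag when it survives the intersections AND its path prevalence in
    that bag reaches ``min_prevalence`` (on a small panel every feature
    pair eventually survives some intersection, but only signal
    combinations ride a majority of decision paths). Stability is the
    fraction of bags recovering the set. Returns all observed interactions
    sorted by (stability, prevalence) descending.
    """
    if n_bags < 2:
        raise ValueError("need at least 2 outer bags")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(X)
    rng = rng or np.random.default_rng()
    counts: dict[frozenset, int] = {}
    prevs: dict[frozenset, list[float]] = {}
    for bag_rng in rng.spawn(n_bags):
        idx = bag_rng.integers(0, n, size=n)
        model = fit_irf(
            X[idx], y[idx], task=task, n_iterations=n_iterations, params=params, rng=bag_rng
        )
        paths = extract_paths(model.forest, class_filter=class_filter)
        if not paths:
            continue
        found = random_intersection_trees(paths, rit=rit, rng=bag_rng)
        for s, prev in found.items():
            if prev < min_prevalence:
                continue
            counts[s] = counts.get(s, 0) + 1
            prevs.setdefault(s, []).append(prev)
    out = [
        Interaction(features=s, prevalence=float(np.mean(prevs[s])), stability=c / n_bags)
        for s, c in counts.items()
    ]
    out.sort(key=lambda i: (-i.stability, -i.prevalence, sorted(i.features)))
    return out


class IterativeRandomForest:
    """Model-object facade over :func:`fit_irf` (statsmodels-style).

    Parameters are stored at construction; ``fit`` consumes a seed or
    generator and returns :class:`IRFResults`.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        task: str = "classification",
        n_iterations: int = 5,
        params: ForestParams | None = None,
        feature_names: list[str] | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.n_iterations = n_iterations
        self.params = params or ForestParams()
        self.feature_names = list(feature_names) if feature_names else [
            f"x{i}" for i in range(self.X.shape[1])
        ]

    def fit(self, seed: int | np.random.Generator | None = None) -> "IRFResults":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        model = fit_irf(
            self.X, self.y, task=self.task, n_iterations=self.n_iterations,
            params=self.params, rng=rng,
        )
        return IRFResults(self, model)


class IRFResults:
    """Fitted iRF with named importances and a text summary."""

    def __init__(self, model: IterativeRandomForest, fitted: IRFModel):
        self.model = model
        self.fitted = fitted

    @property
    def importances_(self) -> np.ndarray:
        return self.fitted.importances_

    def importance_series(self):
        import pandas as pd

        return pd.Series(self.importances_, index=self.model.feature_names).sort_values(
            ascending=False
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.fitted.forest.predict(np.asarray(X, dtype=float))

    def summary(self) -> str:
        imp = self.importance_series()
        lines = [
            f"Iterative random forest ({self.model.task}), "
            f"{self.model.n_iterations} iterations, "
            f"{self.fitted.forest.params.n_trees} trees/iteration",
            "feature importance (impurity decrease, normalized):",
        ]
        lines += [f"  {name:>6s}  {val:.4f}" for name, val in imp.items()]
        return "\n".join(lines)
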