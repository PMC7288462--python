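"""Boosted regression trees for binomial and multinomial allele outcomes.

Stagewise gradient boosting with small least-squares regression trees,
shrinkage, bagging, cross-validated selection of the tree count (deviance
reduction as the measure of success), per-predictor relative influence,
partial dependence, and an adjusted-count pseudo-R2 (one minus the ratio of
the model's cross-validated misclassification frequency to that of the
intercept-only, majority-class predictor).

Bernoulli loss models a binary allele outcome; the multinomial loss (one
tree per class and stage, symmetric logits, softmax normalization) handles
triallelic loci.  Categorical predictors (the region factor) are split by
subset using the ordered-mean heuristic.  Model predictions are determined
by the maximal class probability, ties broken toward the lowest class index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import DataError


@dataclass
class BRTConfig:
    learning_rate: float = 0.01
    max_trees: int = 20_000
    min_trees_guideline: int = 1000
    cv_folds: int = 10
    tree_depth: int = 2
    bag_fraction: float = 0.5
    min_node_size: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise DataError("learning_rate must lie in (0, 1]")
        if self.max_trees < self.cv_folds:
            raise DataError("max_trees must be >= cv_folds")
        if self.tree_depth < 1:
            raise DataError("tree_depth must be >= 1")


# ---------------------------------------------------------------------
# Regression tree on gradient residuals
# ---------------------------------------------------------------------

@dataclass
class _Node:
    # internal node: feature >= 0; leaf: feature == -1 and value set
    feature: int = -1
    threshold: float = 0.0
    cats_left: frozenset | None = None
    left: int = -1
    right: int = -1
    value: float = 0.0
    improvement: float = 0.0


class RegressionTree:
    """Depth-limited least-squares regression tree with per-split
    improvement accounting (used for relative influence)."""

    def __init__(self) -> None:
        self.nodes: list[_Node] = []

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        idx = np.arange(len(X))
        stack = [(0, idx)]
        while stack:
            ni, rows = stack.pop()
            node = self.nodes[ni]
            if node.feature < 0:
                out[rows] = node.value
                continue
            x = X[rows, node.feature]
            if node.cats_left is not None:
                go_left = np.isin(x, list(node.cats_left))
            else:
                go_left = x <= node.threshold
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out

    def leaf_assignment(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X), dtype=int)
        idx = np.arange(len(X))
        stack = [(0, idx)]
        while stack:
            ni, rows = stack.pop()
            node = self.nodes[ni]
            if node.feature < 0:
                out[rows] = ni
                continue
            x = X[rows, node.feature]
            if node.cats_left is not None:
                go_left = np.isin(x, list(node.cats_left))
            else:
                go_left = x <= node.threshold
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out

    def scale_leaves(self, values: dict[int, float]) -> None:
        for ni, v in values.items():
            self.nodes[ni].value = v

    @property
    def splits(self) -> list[tuple[int, float]]:
        return [(n.feature, n.improvement) for n in self.nodes if n.feature >= 0]


def _best_split(x, z, min_node_size, categorical):
    """Best split of one feature; returns (gain, threshold_or_catset)."""
    n = len(z)
    total = z.sum()
    base = total * total / n
    if categorical:
        levels, inv = np.unique(x, return_inverse=True)
        if len(levels) < 2:
            return -np.inf, None
        sums = np.bincount(inv, weights=z)
        counts = np.bincount(inv)
        order = np.argsort(sums / counts)
        csum = np.cumsum(sums[order])
        ccnt = np.cumsum(counts[order])
        best_gain, best_k = -np.inf, None
        for k in range(len(levels) - 1):
            nl, nr = ccnt[k], n - ccnt[k]
            if nl < min_node_size or nr < min_node_size:
                continue
            gain = csum[k] ** 2 / nl + (total - csum[k]) ** 2 / nr - base
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k is None:
            return -np.inf, None
        return best_gain, frozenset(levels[order[: best_k + 1]].tolist())
    order = np.argsort(x, kind="stable")
    xs = x[order]
    zs = z[order]
    csum = np.cumsum(zs)
    # candidate positions: last index of each run of equal x
    change = np.flatnonzero(xs[:-1] != xs[1:])
    if change.size == 0:
        return -np.inf, None
    nl = change + 1
    nr = n - nl
    ok = (nl >= min_node_size) & (nr >= min_node_size)
    if not ok.any():
        return -np.inf, None
    change = change[ok]
    nl, nr = nl[ok], nr[ok]
    sl = csum[change]
    gain = sl**2 / nl + (total - sl) ** 2 / nr - base
    b = int(np.argmax(gain))
    thr = 0.5 * (xs[change[b]] + xs[change[b] + 1])
    return float(gain[b]), float(thr)


def fit_tree(
    residuals: np.ndarray,
    X: np.ndarray,
    depth: int = 2,
    min_node_size: int = 5,
    rows: np.ndarray | None = None,
    cat_features: frozenset | set | None = None,
) -> RegressionTree:
    """Least-squares regression tree on gradient residuals.

    Splits maximize SSE reduction; categorical features use the
    ordered-mean subset heuristic.  Constant residuals give a single-leaf
    tree predicting their mean.
    """
    cat_features = frozenset(cat_features or ())
    rows = np.arange(len(residuals)) if rows is None else np.asarray(rows)
    tree = RegressionTree()

    def grow(idx: np.ndarray, d: int) -> int:
        ni = len(tree.nodes)
        node = _Node(value=float(residuals[idx].mean()) if len(idx) else 0.0)
        tree.nodes.append(node)
        if d >= depth or len(idx) < 2 * min_node_size:
            return ni
        z = residuals[idx]
        if np.ptp(z) == 0:
            return ni
        best = (-np.inf, None, None)
        for f in range(X.shape[1]):
            gain, how = _best_split(X[idx, f], z, min_node_size, f in cat_features)
            if gain > best[0] + 1e-12:
                best = (gain, f, how)
        gain, f, how = best
        if f is None or gain <= 1e-12:
            return ni
        x = X[idx, f]
        if isinstance(how, frozenset):
            go_left = np.isin(x, list(how))
            node.cats_left = how
        else:
            go_left = x <= how
            node.threshold = how
        node.feature = f
        node.improvement = float(gain)
        node.left = grow(idx[go_left], d + 1)
        node.right = grow(idx[~go_left], d + 1)
        return ni

    grow(rows, 0)
    return tree


# ---------------------------------------------------------------------
# Boosted model
# ---------------------------------------------------------------------

@dataclass
class BRTModel:
    loss: str                       # "bernoulli" | "multinomial"
    n_classes: int
    intercept: np.ndarray           # (K,) or (1,)
    trees: list                     # bernoulli: [tree]; multinomial: [[tree_k]]
    config: BRTConfig
    feature_names: list[str]
    cat_features: frozenset
    n_trees_selected: int | None = None
    cv_curve: np.ndarray | None = None
    cv_predictions: np.ndarray | None = None   # MAP class per training row
    train_y: np.ndarray | None = None
    train_X: np.ndarray | None = None
    warnings_: list[str] = field(default_factory=list)

    def decision(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        """Additive scores F(x): shape (n, K) (K=1 for Bernoulli)."""
        X = np.asarray(X, dtype=float)
        m = len(self.trees) if n_trees is None else min(n_trees, len(self.trees))
        if self.n_trees_selected is not None and n_trees is None:
            m = self.n_trees_selected
        F = np.tile(self.intercept, (len(X), 1))
        for stage in self.trees[:m]:
            if self.loss == "bernoulli":
                F[:, 0] += stage.predict(X)
            else:
                for k, tr in enumerate(stage):
                    F[:, k] += tr.predict(X)
        return F

    def predict_proba(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        F = self.decision(X, n_trees)
        if self.loss == "bernoulli":
            p = 1.0 / (1.0 + np.exp(-F[:, 0]))
            return np.column_stack([1 - p, p])
        F = F - F.max(axis=1, keepdims=True)
        e = np.exp(F)
        return e / e.sum(axis=1, keepdims=True)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise DataError("X must be 2-D with one row per observation in y")
    return X, y


def fit_brt(
    X,
    y,
    loss: str = "bernoulli",
    config: BRTConfig | None = None,
    n_trees: int | None = None,
    feature_names=None,
    cat_features=(),
    rng: np.random.Generator | None = None,
) -> BRTModel:
    """Fit a boosted ensemble by stagewise gradient descent.

    Initialization is the intercept-only model (logit of the mean / log
    class proportions); each stage fits tree(s) to the negative gradient
    (``y - p``; per class for the multinomial loss), takes a Newton leaf
    step scaled by the learning rate, and adds them.  Stops at ``n_trees``
    (default ``config.max_trees``).
    """
    config = config or BRTConfig()
    X, y = _check_xy(X, y)
    rng = rng or np.random.default_rng(config.seed)
    n = len(y)
    cat_features = frozenset(cat_features)
    feature_names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    m_total = config.max_trees if n_trees is None else n_trees
    classes = np.unique(y)
    warns: list[str] = []
    if loss == "bernoulli":
        ybin = y.astype(float)
        pbar = float(np.clip(ybin.mean(), 1e-9, 1 - 1e-9))
        F0 = np.array([np.log(pbar / (1 - pbar))])
        model = BRTModel(
            "bernoulli", 2, F0, [], config, feature_names, cat_features,
            train_y=y.copy(), train_X=X,
        )
        if len(classes) < 2:
            warns.append("single-class response: intercept-only model")
            model.warnings_ = warns
            return model
        F = np.full(n, F0[0])
        bag_n = max(2 * config.min_node_size, int(round(config.bag_fraction * n)))
        for _ in range(m_total):
            p = 1.0 / (1.0 + np.exp(-F))
            z = ybin - p
            bag = rng.choice(n, size=min(bag_n, n), replace=False)
            tree = fit_tree(
                z, X, config.tree_depth, config.min_node_size, rows=bag,
                cat_features=cat_features,
            )
            leaves = tree.leaf_assignment(X)
            vals = {}
            w = p * (1 - p)
            for leaf in np.unique(leaves[bag]):
                in_leaf = bag[leaves[bag] == leaf]
                denom = w[in_leaf].sum()
                gamma = z[in_leaf].sum() / max(denom, 1e-9)
                vals[int(leaf)] = config.learning_rate * float(np.clip(gamma, -4, 4))
            for ni in range(len(tree.nodes)):
                if tree.nodes[ni].feature < 0 and ni not in vals:
                    vals[ni] = 0.0
            tree.scale_leaves(vals)
            F += tree.predict(X)
            model.trees.append(tree)
        model.warnings_ = warns
        return model
    if loss != "multinomial":
        raise DataError(f"unknown loss {loss!r}")
    K = int(max(3, len(classes)))
    yi = y.astype(int)
    counts = np.bincount(yi, minlength=K).astype(float)
    props = np.clip(counts / counts.sum(), 1e-9, 1)
    F0 = np.log(props)
    Y = np.zeros((n, K))
    Y[np.arange(n), yi] = 1.0
    model = BRTModel(
        "multinomial", K, F0, [], config, feature_names, cat_features,
        train_y=y.copy(), train_X=X,
    )
    if len(classes) < 2:
        warns.append("single-class response: intercept-only model")
        model.warnings_ = warns
        return model
    F = np.tile(F0, (n, 1))
    bag_n = max(2 * config.min_node_size, int(round(config.bag_fraction * n)))
    for _ in range(m_total):
        Fs = F - F.max(axis=1, keepdims=True)
        e = np.exp(Fs)
        P = e / e.sum(axis=1, keepdims=True)
        Z = Y - P
        bag = rng.choice(n, size=min(bag_n, n), replace=False)
        stage = []
        for k in range(K):
            z = Z[:, k]
            tree = fit_tree(
                z, X, config.tree_depth, config.min_node_size, rows=bag,
                cat_features=cat_features,
            )
            leaves = tree.leaf_assignment(X)
            vals = {}
            for leaf in np.unique(leaves[bag]):
                in_leaf = bag[leaves[bag] == leaf]
                num = z[in_leaf].sum()
                den = (np.abs(z[in_leaf]) * (1 - np.abs(z[in_leaf]))).sum()
                gamma = (K - 1) / K * num / max(den, 1e-9)
                vals[int(leaf)] = config.learning_rate * float(np.clip(gamma, -4, 4))
            for ni in range(len(tree.nodes)):
                if tree.nodes[ni].feature < 0 and ni not in vals:
                    vals[ni] = 0.0
            tree.scale_leaves(vals)
            F[:, k] += tree.predict(X)
            stage.append(tree)
        model.trees.append(stage)
    model.warnings_ = warns
    return model


def deviance(model_or_loss, y, proba: np.ndarray) -> float:
    """Mean deviance of predicted probabilities against outcomes."""
    y = np.asarray(y).astype(int)
    p = np.clip(proba[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-2.0 * np.mean(np.log(p)))


def _stratified_folds(n, cv_folds, rng, groups=None):
    """Fold assignment stratified by group (population) to keep every fold
    representative of every site."""
    fold = np.empty(n, dtype=int)
    if groups is None:
        idx = rng.permutation(n)
        fold[idx] = np.arange(n) % cv_folds
        return fold
    groups = np.asarray(groups)
    offset = 0
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        rows = rng.permutation(rows)
        fold[rows] = (np.arange(len(rows)) + offset) % cv_folds
        offset += len(rows)
    return fold


def cv_select_trees(
    X,
    y,
    loss: str = "bernoulli",
    config: BRTConfig | None = None,
    groups=None,
    feature_names=None,
    cat_features=(),
):
    """Select the tree count by fold-stratified cross-validation.

    Returns ``(n_opt, cv_curve, cv_map_predictions)`` where the curve is the
    mean held-out deviance per tree count and predictions are held-out MAP
    classes at ``n_opt``.  Warns when the optimum is below the 1000-tree
    rule of thumb or hits the ``max_trees`` cap.
    """
    config = config or BRTConfig()
    if config.cv_folds < 2:
        raise DataError("cv_folds must be >= 2")
    X, y = _check_xy(X, y)
    n = len(y)
    if n < config.cv_folds:
        raise DataError("fewer observations than CV folds")
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(n, config.cv_folds, rng, groups)
    curves = np.zeros((config.cv_folds, config.max_trees + 1))
    fold_models = []
    for f in range(config.cv_folds):
        tr = folds != f
        te = ~tr
        m = fit_brt(
            X[tr], y[tr], loss=loss, config=config,
            feature_names=feature_names, cat_features=cat_features,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        fold_models.append((m, te))
        # incremental held-out deviance per tree count
        F = np.tile(m.intercept, (te.sum(), 1))
        Xte, yte = X[te], y[te]
        curves[f, 0] = _dev_from_F(m.loss, F, yte)
        for t, stage in enumerate(m.trees, start=1):
            if m.loss == "bernoulli":
                F[:, 0] += stage.predict(Xte)
            else:
                for k, trk in enumerate(stage):
                    F[:, k] += trk.predict(Xte)
            curves[f, t] = _dev_from_F(m.loss, F, yte)
        if len(m.trees) < config.max_trees:  # degenerate single-class fold
            curves[f, len(m.trees) + 1:] = curves[f, len(m.trees)]
    curve = curves.mean(axis=0)
    n_opt = int(np.argmin(curve))
    if n_opt == config.max_trees:
        warnings.warn("CV optimum hit the max_trees cap")
    elif n_opt < config.min_trees_guideline:
        warnings.warn(
            f"CV-optimal tree count {n_opt} is below the "
            f"{config.min_trees_guideline}-tree rule of thumb"
        )
    # held-out MAP predictions at the optimum
    pred = np.empty(n, dtype=int)
    for m, te in fold_models:
        proba = m.predict_proba(X[te], n_trees=n_opt)
        pred[te] = proba.argmax(axis=1)
    return n_opt, curve, pred


def _dev_from_F(loss, F, y):
    if loss == "bernoulli":
        p = 1.0 / (1.0 + np.exp(-F[:, 0]))
        proba = np.column_stack([1 - p, p])
    else:
        Fs = F - F.max(axis=1, keepdims=True)
        e = np.exp(Fs)
        proba = e / e.sum(axis=1, keepdims=True)
    return deviance(loss, y, proba)


def predict(model: BRTModel, X, n_trees: int | None = None):
    """Class probabilities and MAP class (lowest index wins ties)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise DataError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    proba = model.predict_proba(X, n_trees)
    return proba, proba.argmax(axis=1)


def pseudo_r2(cv_map_predictions, y) -> float:
    """Adjusted-count pseudo-R2: ``1 - err_M / err_0`` where ``err_M`` is
    the CV misclassification frequency and ``err_0`` that of the
    majority-class (intercept-only) predictor.  NaN when ``err_0`` is 0."""
    y = np.asarray(y).astype(int)
    pred = np.asarray(cv_map_predictions).astype(int)
    err_m = float((pred != y).mean())
    majority = np.bincount(y).argmax()
    err_0 = float((y != majority).mean())
    if err_0 == 0:
        return float("nan")
    return 1.0 - err_m / err_0


def relative_influence(model: BRTModel, n_trees: int | None = None) -> np.ndarray:
    """Per-predictor relative influence (%): normalized sums of squared-
    error improvements over all splits using each predictor (averaged over
    class trees for the multinomial loss).  All-zero with an intercept-only
    model."""
    imp = np.zeros(len(model.feature_names))
    m = len(model.trees) if n_trees is None else min(n_trees, len(model.trees))
    if model.n_trees_selected is not None and n_trees is None:
        m = model.n_trees_selected
    for stage in model.trees[:m]:
        trees = [stage] if model.loss == "bernoulli" else stage
        for tr in trees:
            for f, gain in tr.splits:
                imp[f] += gain
    total = imp.sum()
    if total <= 0:
        return imp  # flagged by all-zero profile
    return 100.0 * imp / total


def partial_dependence(
    model: BRTModel,
    feature: int | str,
    grid,
    class_index: int = 1,
    n_trees: int | None = None,
) -> np.ndarray:
    """Probability-scale partial-dependence curve: for each grid value the
    prediction averaged over training rows with the predictor forced to it."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DataError("empty partial-dependence grid")
    if isinstance(feature, str):
        feature = model.feature_names.index(feature)
    X = model.train_X
    if X is None:
        raise DataError("model lacks stored training rows")
    out = np.empty(len(grid))
    for i, v in enumerate(grid):
        Xv = X.copy()
        Xv[:, feature] = v
        proba = model.predict_proba(Xv, n_trees)
        out[i] = float(proba[:, class_index].mean())
    return out
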