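"""Stochastic gradient boosting of small regression trees on log-odds.

Binary classification in the TreeNet tradition: the model is an additive
expansion f(x) = f0 + nu * sum_m T_m(x) on the log-odds scale, fitted by
stage-wise least-squares trees on the logistic pseudo-residuals y - p,
with each tree grown best-first to at most ``max_leaves`` terminal nodes
on a random half of the training sample, and leaf values set by a single
Newton step  sum(y - p) / sum(p (1 - p)).  Test-set ROC area and
misclassification rate are recorded every stage; the ensemble size is
the stage that maximises test ROC area (ties favour fewer trees).

Categorical features (e.g. forest type) are split by the CART device:
categories are ordered by their mean pseudo-residual inside the node and
then treated as ordered.  Missing values are routed to the child that
received more training weight.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import roc_auc

logger = logging.getLogger(__name__)

LABEL_COLUMN = "label"
POSITIVE_CLASS = "infested"


@dataclass
class GBTConfig:
    n_trees: int = 500
    max_leaves: int = 6
    learning_rate: float = 0.01
    subsample: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.max_leaves < 2:
            raise ValueError("max_leaves must be >= 2")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")


@dataclass
class _Node:
    value: float = 0.0
    feature: int = -1
    threshold: float = math.nan
    left_cats: frozenset | None = None
    default_left: bool = True
    gain: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class RegressionTree:
    root: _Node
    n_leaves: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        stack = [(self.root, np.arange(X.shape[0]))]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if node.is_leaf:
                out[rows] = node.value
                continue
            x = X[rows, node.feature]
            if node.left_cats is not None:
                left = np.isin(x, list(node.left_cats))
                known = np.isfinite(x) & np.isin(x, list(node.left_cats) + _right_cats(node))
            else:
                left = x <= node.threshold
                known = np.isfinite(x)
            go_left = np.where(known, left, node.default_left)
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out

    def feature_gains(self, n_features: int) -> np.ndarray:
        g = np.zeros(n_features)
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                g[node.feature] += node.gain
                stack.extend([node.left, node.right])
        return g


def _right_cats(node: _Node) -> list:
    rc = getattr(node, "_right_cats", None)
    return rc if rc is not None else []


@dataclass
class BoostedEnsemble:
    """Fitted additive log-odds model with its per-stage test trajectory."""

    f0: float
    trees: list[RegressionTree | None]
    learning_rate: float
    n_trees_optimal: int
    per_iteration: pd.DataFrame
    feature_names: tuple[str, ...]
    categorical_features: frozenset[str]
    train_matrix: np.ndarray = field(repr=False, default=None)
    config: GBTConfig | None = None

    def predict_raw(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        n = self.n_trees_optimal if n_trees is None else n_trees
        f = np.full(X.shape[0], self.f0)
        for tree in self.trees[:n]:
            if tree is not None:
                f += self.learning_rate * tree.predict(X)
        return f


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def design_matrix(
    table: pd.DataFrame, feature_names, categorical: frozenset[str]
) -> np.ndarray:
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks column(s): {missing}")
    X = np.empty((len(table), len(feature_names)))
    for j, name in enumerate(feature_names):
        col = table[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            codes = col.cat.codes.astype(float).to_numpy()
            X[:, j] = np.where(codes < 0, np.nan, codes)
        else:
            X[:, j] = pd.to_numeric(col, errors="raise").astype(float)
    return X


def _labels_to_y(table: pd.DataFrame) -> np.ndarray:
    return (table[LABEL_COLUMN].to_numpy() == POSITIVE_CLASS).astype(float)


def stratified_split(
    table: pd.DataFrame, test_fraction: float = 1.0 / 3.0, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class random split preserving class proportions within 1 object."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, grp in table.groupby(LABEL_COLUMN, sort=True):
        if len(grp) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 objects")
        n_test = int(round(len(grp) * test_fraction))
        n_test = min(max(n_test, 1), len(grp) - 1)
        perm = rng.permutation(len(grp))
        test_idx.extend(grp.index[perm[:n_test]])
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()


# ---------------------------------------------------------------------------
# tree induction
# ---------------------------------------------------------------------------

def _best_split(X, r, rows, feature_order, categorical_idx):
    """Best single split of `rows` by squared-error improvement.

    Ties break to the earlier feature in column order, then the smaller
    threshold (guaranteed by scanning features in order and thresholds
    ascending with strict improvement).
    """
    best = None  # (gain, feature, threshold|left_cats, default_left)
    r_rows = r[rows]
    for j in feature_order:
        x = X[rows, j]
        finite = np.isfinite(x)
        if finite.sum() < 2:
            continue
        xf, rf = x[finite], r_rows[finite]
        if j in categorical_idx:
            cats, inv = np.unique(xf, return_inverse=True)
            if cats.size < 2:
                continue
            sums = np.bincount(inv, weights=rf)
            cnts = np.bincount(inv)
            order = np.lexsort((cats, sums / cnts))  # mean residual, then code
            rank = np.empty(cats.size, dtype=np.int64)
            rank[order] = np.arange(cats.size)
            xs_key = rank[inv].astype(float)
        else:
            xs_key = xf
        sort = np.argsort(xs_key, kind="mergesort")
        xs, rs = xs_key[sort], rf[sort]
        csum = np.cumsum(rs)
        total, n = csum[-1], xs.size
        boundary = np.nonzero(xs[:-1] < xs[1:])[0]
        if boundary.size == 0:
            continue
        nl = boundary + 1.0
        sl = csum[boundary]
        gains = sl**2 / nl + (total - sl) ** 2 / (n - nl) - total**2 / n
        k = int(np.argmax(gains))  # first max -> smallest threshold
        if best is None or gains[k] > best[0] + 1e-12:
            if j in categorical_idx:
                # ranks left of the boundary identify the left category set
                n_left_cats = int(xs[boundary[k]]) + 1
                left_set = frozenset(cats[order[:n_left_cats]].tolist())
                right_set = [c for c in cats.tolist() if c not in left_set]
                split = (left_set, tuple(right_set))
            else:
                split = ((xs[boundary[k]] + xs[boundary[k] + 1]) / 2.0, None)
            best = (float(gains[k]), j, split, bool(nl[k] >= n - nl[k]))
    return best


def _route(X, rows, node) -> tuple[np.ndarray, np.ndarray]:
    x = X[rows, node.feature]
    if node.left_cats is not None:
        known = np.isfinite(x)
        left = np.isin(x, list(node.left_cats))
    else:
        known = np.isfinite(x)
        left = x <= node.threshold
    go_left = np.where(known, left, node.default_left)
    return rows[go_left], rows[~go_left]


def _fit_tree(X, r, hess, rows, max_leaves, categorical_idx) -> RegressionTree:
    feature_order = range(X.shape[1])
    root = _Node()
    leaf_rows = {id(root): rows}
    leaves = [root]
    heap = []
    counter = 0

    def push(node):
        nonlocal counter
        rws = leaf_rows[id(node)]
        if rws.size < 2:
            return
        cand = _best_split(X, r, rws, feature_order, categorical_idx)
        if cand is not None and cand[0] > 1e-12:
            heapq.heappush(heap, (-cand[0], counter, node, cand))
            counter += 1

    push(root)
    while heap and len(leaves) < max_leaves:
        _, _, node, (gain, j, split, default_left) = heapq.heappop(heap)
        if not node.is_leaf:
            continue
        node.feature = j
        node.gain = gain
        node.default_left = default_left
        if split[1] is not None or isinstance(split[0], frozenset):
            node.left_cats = split[0]
            node._right_cats = list(split[1])
            node.threshold = math.nan
        else:
            node.threshold = split[0]
        node.left, node.right = _Node(), _Node()
        lrows, rrows = _route(X, leaf_rows.pop(id(node)), node)
        leaf_rows[id(node.left)] = lrows
        leaf_rows[id(node.right)] = rrows
        leaves.remove(node)
        leaves.extend([node.left, node.right])
        push(node.left)
        push(node.right)

    for leaf in leaves:
        rws = leaf_rows[id(leaf)]
        denom = hess[rws].sum()
        leaf.value = float(r[rws].sum() / denom) if denom > 1e-12 else 0.0
    return RegressionTree(root=root, n_leaves=len(leaves))


# ---------------------------------------------------------------------------
# boosting loop
# ---------------------------------------------------------------------------

def _sigmoid(f: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(f, -35, 35)))


def fit_gbt(
    train: pd.DataFrame,
    test: pd.DataFrame,
    config: GBTConfig | None = None,
    categorical_features: tuple[str, ...] = ("forest_type",),
) -> BoostedEnsemble:
    """Fit the boosted log-odds classifier and track test performance.

    ``train``/``test`` are feature tables with a ``label`` column.  The
    optimal ensemble size is chosen by test ROC area.
    """
    config = config or GBTConfig()
    feature_names = tuple(c for c in train.columns if c != LABEL_COLUMN)
    categorical = frozenset(f for f in categorical_features if f in feature_names)
    cat_idx = frozenset(feature_names.index(f) for f in categorical)

    Xtr = design_matrix(train, feature_names, categorical)
    Xte = design_matrix(test, feature_names, categorical)
    ytr, yte = _labels_to_y(train), _labels_to_y(test)
    if ytr.min() == ytr.max():
        raise ValueError("training set must contain both classes")

    p_hat = ytr.mean()
    f0 = math.log(p_hat / (1.0 - p_hat))
    f_tr = np.full(ytr.size, f0)
    f_te = np.full(yte.size, f0)
    rng = np.random.default_rng(config.seed)
    n_sub = max(2, int(round(config.subsample * ytr.size)))

    trees: list[RegressionTree | None] = []
    records = []
    te_labels = test[LABEL_COLUMN].to_numpy()
    for m in range(config.n_trees):
        sub = np.sort(rng.permutation(ytr.size)[:n_sub])
        p = _sigmoid(f_tr)
        if ytr[sub].min() == ytr[sub].max():
            logger.warning("stage %d: single-class subsample, stage skipped", m + 1)
            trees.append(None)
        else:
            r = ytr - p
            hess = p * (1.0 - p)
            tree = _fit_tree(Xtr, r, hess, sub, config.max_leaves, cat_idx)
            trees.append(tree)
            f_tr += config.learning_rate * tree.predict(Xtr)
            f_te += config.learning_rate * tree.predict(Xte)
        p_tr = _sigmoid(f_tr)
        eps = 1e-12
        deviance = float(
            -np.mean(ytr * np.log(p_tr + eps) + (1 - ytr) * np.log(1 - p_tr + eps))
        )
        auc = roc_auc(te_labels, f_te)
        mis = float(np.mean((f_te > 0) != (yte == 1)))
        records.append((m + 1, auc, mis, deviance))

    per_iter = pd.DataFrame(
        records, columns=["n_trees", "test_auc", "test_misclass", "train_deviance"]
    )
    if per_iter.empty:
        n_opt = 0
    else:
        # optimal size: maximal test ROC area.  On a finite test set the
        # ROC area is quantized in steps of 1/(n+ * n-), so stages within
        # one concordant-pair quantum of the maximum are ties; ties are
        # resolved by the test misclassification rate, then fewer trees.
        n_pos = int((yte == 1).sum())
        n_neg = yte.size - n_pos
        auc_tol = 1.0 / (n_pos * n_neg)
        auc = per_iter["test_auc"].to_numpy()
        tied = np.nonzero(auc >= auc.max() - auc_tol)[0]
        mis = per_iter["test_misclass"].to_numpy()[tied]
        best = tied[np.lexsort((per_iter["n_trees"].to_numpy()[tied], mis))[0]]
        n_opt = int(per_iter["n_trees"].iloc[best])
    return BoostedEnsemble(
        f0=f0,
        trees=trees,
        learning_rate=config.learning_rate,
        n_trees_optimal=n_opt,
        per_iteration=per_iter,
        feature_names=feature_names,
        categorical_features=categorical,
        train_matrix=Xtr,
        config=config,
    )


def predict_logodds(
    model: BoostedEnsemble, table: pd.DataFrame, n_trees: int | None = None
) -> pd.Series:
    """Log-odds score per object; positive means infested."""
    X = design_matrix(table, model.feature_names, model.categorical_features)
    return pd.Series(model.predict_raw(X, n_trees), index=table.index, name="logodds")


def classify(model: BoostedEnsemble, table: pd.DataFrame) -> pd.Series:
    scores = predict_logodds(model, table)
    lab = np.where(scores > 0, POSITIVE_CLASS, "healthy")
    return pd.Series(lab, index=table.index, name="predicted")


def variable_importance(model: BoostedEnsemble) -> pd.DataFrame:
    """Split-gain importance over the optimal ensemble, rescaled to top=100."""
    gains = np.zeros(len(model.feature_names))
    for tree in model.trees[: model.n_trees_optimal]:
        if tree is not None:
            gains += tree.feature_gains(gains.size)
    top = gains.max()
    scaled = 100.0 * gains / top if top > 0 else gains
    df = pd.DataFrame({"feature": model.feature_names, "importance": scaled})
    return df.sort_values("importance", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def select_top_features(importance: pd.DataFrame, threshold_pct: float = 15.0) -> list[str]:
    """Features whose rescaled importance reaches the threshold (top always does)."""
    keep = importance.loc[importance["importance"] >= threshold_pct, "feature"]
    return keep.tolist()


def partial_dependence(
    model: BoostedEnsemble, feature: str, grid=None, n_grid: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Centered average log-odds as one feature sweeps its observed range.

    For categorical features the grid is the observed category set and
    unknown categories are rejected.
    """
    if feature not in model.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = model.feature_names.index(feature)
    col = model.train_matrix[:, j]
    observed = col[np.isfinite(col)]
    if feature in model.categorical_features:
        cats = np.unique(observed)
        if grid is None:
            grid = cats
        else:
            grid = np.asarray(grid, dtype=float)
            unknown = set(grid.tolist()) - set(cats.tolist())
            if unknown:
                raise ValueError(f"unknown categories for {feature}: {sorted(unknown)}")
    elif grid is None:
        grid = np.linspace(observed.min(), observed.max(), n_grid)
    else:
        grid = np.asarray(grid, dtype=float)

    X = model.train_matrix.copy()
    values = np.empty(len(grid))
    for k, v in enumerate(grid):
        X[:, j] = v
        values[k] = model.predict_raw(X).mean()
    return np.asarray(grid, dtype=float), values - values.mean()
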