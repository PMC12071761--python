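"""CART: binary classification trees with Gini splitting and
cost-complexity pruning.

The tree is grown by exhaustive binary recursive splitting: at each node
every feature is scanned and candidate thresholds are the midpoints between
consecutive distinct sorted values; the split minimizing the
sample-weighted child Gini impurity

    Gini(D) = 1 - sum_k p_k^2

is taken (ties broken by lowest feature index, then smallest threshold).
Samples with ``feature <= threshold`` go left.

Overfitting is controlled by weakest-link cost-complexity pruning: for
every internal node t,

    beta_t = (R(t) - R(T_t)) / (N_{T_t} - 1)

where R(t) is the resubstitution misclassification cost of t as a leaf,
R(T_t) that of the subtree rooted at t, and N_{T_t} its leaf count — all
costs measured as proportions of the full training set.  Collapsing every
node attaining the minimal beta and iterating yields the nested subtree
sequence T0, T1, ..., Tn (root only); the final subtree is selected by
stratified cross-validation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CartConfig",
    "CartNode",
    "CartTree",
    "gini_index",
    "best_split",
    "grow_tree",
    "predict_tree",
    "weakest_link_sequence",
    "prune_at_alpha",
    "select_subtree_cv",
]


@dataclass(frozen=True)
class CartConfig:
    """Growth and pruning safeguards.

    ``gini_split_threshold``: a node whose impurity is already below this
    value becomes a leaf.  ``cv_folds_for_pruning`` controls subtree
    selection; ``seed`` makes fold assignment deterministic.
    """

    gini_split_threshold: float = 0.01
    min_samples_split: int = 2
    max_depth: int = 20
    cv_folds_for_pruning: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gini_split_threshold <= 0 or self.min_samples_split <= 0 \
                or self.max_depth <= 0 or self.cv_folds_for_pruning <= 0:
            raise ValueError("all CartConfig fields must be positive")


@dataclass
class CartNode:
    class_counts: np.ndarray  # training samples per class reaching the node
    node_error: float  # R(t): misclassification proportion of full train set
    split_feature: Optional[int] = None
    split_threshold: Optional[float] = None
    left: Optional["CartNode"] = None
    right: Optional["CartNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def prediction(self) -> int:
        # ties -> lowest class index (argmax convention)
        return int(np.argmax(self.class_counts))

    def leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.leaves() + self.right.leaves()

    def subtree_error(self) -> float:
        """R(T_t): summed leaf misclassification cost of the subtree."""
        if self.is_leaf:
            return self.node_error
        return self.left.subtree_error() + self.right.subtree_error()


@dataclass
class CartTree:
    root: CartNode
    classes: np.ndarray  # label values, sorted; predictions index into this
    n_total: int  # training-set size used for cost normalization
    config: CartConfig = field(default_factory=CartConfig)

    def n_leaves(self) -> int:
        return self.root.leaves()

    def training_error(self) -> float:
        return self.root.subtree_error()

    def copy(self) -> "CartTree":
        return CartTree(
            root=copy.deepcopy(self.root), classes=self.classes,
            n_total=self.n_total, config=self.config,
        )

    def to_dict(self) -> dict:
        """JSON-serializable structure summary."""
        def walk(node: CartNode) -> dict:
            d = {
                "class_counts": [int(c) for c in node.class_counts],
                "node_error": node.node_error,
            }
            if not node.is_leaf:
                d["split_feature"] = int(node.split_feature)
                d["split_threshold"] = float(node.split_threshold)
                d["left"] = walk(node.left)
                d["right"] = walk(node.right)
            return d

        return {
            "classes": [str(c) for c in self.classes],
            "n_total": self.n_total,
            "n_leaves": self.n_leaves(),
            "root": walk(self.root),
        }


def gini_index(class_counts) -> float:
    """Gini impurity ``1 - sum_k p_k^2``; in [0, 1 - 1/K]."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("class counts sum to zero")
    pk = counts / total
    return float(1.0 - np.sum(pk**2))


def best_split(X: np.ndarray, y_idx: np.ndarray, n_classes: int):
    """Exhaustive search for the impurity-minimizing binary split.

    Returns ``(feature, threshold, weighted_gini)`` or ``None`` when no
    feature admits a split (all columns constant).  Candidate thresholds
    are midpoints of consecutive distinct sorted values; the weighted child
    impurity ``(n_L Gini_L + n_R Gini_R) / n`` is minimized with ties
    broken by lowest feature index then smallest threshold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, n_feat = X.shape
    if n < 2:
        return None
    best = None  # (gini, feature, threshold)
    for j in range(n_feat):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y_idx[order]
        # cumulative class counts for prefix [0, i)
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        total = cum[-1]
        # split allowed between i-1 and i where value changes
        change = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
        if change.size == 0:
            continue
        left = cum[change]
        right = total - left
        nl = left.sum(axis=1)
        nr = right.sum(axis=1)
        gini_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        weighted = (nl * gini_l + nr * gini_r) / n
        k = int(np.argmin(weighted))  # first minimum -> smallest threshold
        thr = 0.5 * (xs[change[k]] + xs[change[k] + 1])
        cand = (float(weighted[k]), j, float(thr))
        if best is None or cand[0] < best[0] - 1e-15:
            best = cand
    if best is None:
        return None
    g, j, thr = best
    return j, thr, g


def _grow(X, y_idx, n_classes, n_total, config, depth) -> CartNode:
    counts = np.bincount(y_idx, minlength=n_classes).astype(float)
    node = CartNode(
        class_counts=counts,
        node_error=float(counts.sum() - counts.max()) / n_total,
    )
    n_here = int(counts.sum())
    if (
        gini_index(counts) < config.gini_split_threshold
        or n_here < config.min_samples_split
        or depth >= config.max_depth
    ):
        return node
    split = best_split(X, y_idx, n_classes)
    if split is None:
        return node
    j, thr, _ = split
    mask = X[:, j] <= thr
    node.split_feature = j
    node.split_threshold = thr
    node.left = _grow(X[mask], y_idx[mask], n_classes, n_total, config, depth + 1)
    node.right = _grow(X[~mask], y_idx[~mask], n_classes, n_total, config, depth + 1)
    return node


def grow_tree(X: np.ndarray, y, config: Optional[CartConfig] = None) -> CartTree:
    """Grow an unpruned tree by recursive Gini splitting."""
    config = config or CartConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes, y_idx = np.unique(np.asarray(y).astype(str), return_inverse=True)
    root = _grow(X, y_idx, classes.size, X.shape[0], config, depth=0)
    return CartTree(root=root, classes=classes, n_total=X.shape[0], config=config)


def predict_tree(tree: CartTree, X: np.ndarray) -> np.ndarray:
    """Predicted labels for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(X.shape[0], dtype=object)
    for i, x in enumerate(X):
        node = tree.root
        while not node.is_leaf:
            node = node.left if x[node.split_feature] <= node.split_threshold else node.right
        out[i] = tree.classes[node.prediction]
    return out


def _internal_betas(node: CartNode, acc: list) -> None:
    if node.is_leaf:
        return
    n_leaves = node.leaves()
    beta = (node.node_error - node.subtree_error()) / (n_leaves - 1)
    acc.append((beta, node))
    _internal_betas(node.left, acc)
    _internal_betas(node.right, acc)


def _collapse(node: CartNode) -> None:
    node.split_feature = None
    node.split_threshold = None
    node.left = None
    node.right = None


def weakest_link_sequence(tree: CartTree):
    """Nested subtree sequence from weakest-link pruning.

    Returns ``(trees, betas)``: ``trees[0]`` is a copy of the input,
    ``trees[-1]`` the root-only tree, and ``betas[k]`` the critical
    complexity value at which ``trees[k+1]`` replaced ``trees[k]``
    (non-decreasing).  A tree that is already a single leaf yields a
    one-element sequence with no betas.
    """
    current = tree.copy()
    trees = [current.copy()]
    betas: list[float] = []
    while not current.root.is_leaf:
        acc: list = []
        _internal_betas(current.root, acc)
        beta_min = min(b for b, _ in acc)
        # Collapse every node attaining beta_min (within fp tolerance);
        # prune bottom-up implicitly: collapsing a node removes its
        # descendants from the tree, so only surviving attainers matter.
        for b, node in acc:
            if b <= beta_min + 1e-12 and not node.is_leaf:
                _collapse(node)
        betas.append(beta_min)
        trees.append(current.copy())
    return trees, betas


def prune_at_alpha(tree: CartTree, alpha: float) -> CartTree:
    """Smallest subtree whose weakest link exceeds ``alpha``."""
    current = tree.copy()
    while not current.root.is_leaf:
        acc: list = []
        _internal_betas(current.root, acc)
        beta_min = min(b for b, _ in acc)
        if beta_min > alpha + 1e-12:
            break
        for b, node in acc:
            if b <= beta_min + 1e-12 and not node.is_leaf:
                _collapse(node)
    return current


def _stratified_assignments(y_idx: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    assign = np.empty(y_idx.size, dtype=int)
    for k in np.unique(y_idx):
        idx = np.nonzero(y_idx == k)[0]
        if idx.size < n_folds:
            raise ValueError(
                f"class {k} has {idx.size} samples; needs >= {n_folds} for pruning CV"
            )
        perm = rng.permutation(idx)
        assign[perm] = np.arange(perm.size) % n_folds
    return assign


def select_subtree_cv(X: np.ndarray, y, config: Optional[CartConfig] = None) -> CartTree:
    """Grow, prune, and pick the subtree with the best cross-validated
    accuracy.

    The full tree's pruning sequence defines candidate complexity values
    (geometric means of consecutive betas, the standard CART convention);
    each candidate is scored by stratified k-fold accuracy of trees grown
    on the fold-train data and pruned at that complexity.  Ties prefer the
    larger complexity (smaller tree).  Deterministic given ``config.seed``.
    """
    config = config or CartConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(str)
    classes, y_idx = np.unique(y, return_inverse=True)

    full = grow_tree(X, y, config)
    trees, betas = weakest_link_sequence(full)
    if len(trees) == 1:
        return full
    # Representative alpha for subtree k (appearing at betas[k-1]): the
    # geometric mean of the interval [betas[k-1], betas[k]] it survives on.
    b = np.clip(np.asarray(betas), 0.0, None)
    alphas = [0.0]
    for k in range(1, len(trees)):
        if k < len(b):
            alphas.append(float(np.sqrt(b[k - 1] * max(b[k], b[k - 1]))))
        else:
            alphas.append(float(b[k - 1]))
    assign = _stratified_assignments(y_idx, config.cv_folds_for_pruning, config.seed)
    scores = np.zeros(len(alphas))
    for f in range(config.cv_folds_for_pruning):
        tr, te = assign != f, assign == f
        fold_tree = grow_tree(X[tr], y[tr], config)
        for k, alpha in enumerate(alphas):
            pruned = prune_at_alpha(fold_tree, alpha)
            scores[k] += float(np.mean(predict_tree(pruned, X[te]) == y[te]))
    # ties -> smaller tree = larger k; scan from the end
    best_k = len(scores) - 1 - int(np.argmax(scores[::-1] == scores.max()))
    return trees[best_k]
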