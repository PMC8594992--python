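"""Classification trees by binary recursive partitioning (CART).

Implements the classic four-step procedure: greedy growth by impurity
reduction (Gini or entropy), growth to exhaustion, weakest-link
cost-complexity pruning, and best-subtree selection by stratified
cross-validated misclassification error (no 1-SE rule: the subtree with the
lowest estimated prediction error wins, ties to the smaller tree).

Conventions: thresholds are midpoints between consecutive distinct values;
"<= threshold" routes left; ties in impurity decrease break to the lowest
predictor index, then the smallest threshold; majority-label ties in a leaf
resolve to the positive class (bTT).  Entropy uses natural logarithms (the
base only rescales, never reorders, candidate splits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "CartNode",
    "CartTree",
    "PrunedSequence",
    "gini_impurity",
    "entropy_impurity",
    "grow_cart",
    "cost_complexity_prune",
    "select_subtree_cv",
    "predict_cart",
    "leaf_scores",
    "stratified_folds",
]


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.size != 2 or np.any(c < 0):
        raise ValueError("counts must be a pair of non-negative integers")
    if c.sum() == 0:
        raise ValueError("empty node has no impurity")
    return c


def gini_impurity(counts) -> float:
    """1 - sum p_c^2 over the two class proportions."""
    c = _check_counts(counts)
    p = c / c.sum()
    return float(1.0 - np.sum(p**2))


def entropy_impurity(counts) -> float:
    """-sum p_c log p_c (natural log), with 0 log 0 = 0."""
    c = _check_counts(counts)
    p = c / c.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


IMPURITIES: dict[str, Callable] = {"gini": gini_impurity,
                                   "entropy": entropy_impurity}


class CartNode:
    __slots__ = ("depth", "var", "threshold", "left", "right",
                 "counts", "majority")

    def __init__(self, depth: int, counts: tuple[int, int]):
        self.depth = depth
        self.counts = counts  # (n class 0, n class 1)
        # fixed tie-break: equal counts resolve to the positive class
        self.majority = 1 if counts[1] >= counts[0] else 0
        self.var: int | None = None
        self.threshold: float | None = None
        self.left: "CartNode | None" = None
        self.right: "CartNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    @property
    def n(self) -> int:
        return int(self.counts[0] + self.counts[1])

    @property
    def misclassified(self) -> int:
        return int(min(self.counts))

    def copy(self) -> "CartNode":
        node = CartNode(self.depth, self.counts)
        node.var, node.threshold = self.var, self.threshold
        if not self.is_leaf:
            node.left = self.left.copy()
            node.right = self.right.copy()
        return node


class CartTree:
    def __init__(self, root: CartNode, n_train: int):
        self.root = root
        self.n_train = n_train

    def copy(self) -> "CartTree":
        return CartTree(self.root.copy(), self.n_train)

    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def leaves(self) -> list[CartNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def internal_nodes(self) -> list[CartNode]:
        return [n for n in self.nodes() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def resubstitution_risk(self) -> float:
        """Training misclassification rate of the tree's leaf labels."""
        return sum(l.misclassified for l in self.leaves()) / self.n_train

    def route(self, X: np.ndarray) -> list[CartNode]:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("samples with missing predictors are rejected")
        out = []
        for row in np.atleast_2d(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.var] <= node.threshold else node.right
            out.append(node)
        return out

    def structure(self):
        def rec(node):
            if node.is_leaf:
                return ("leaf", node.majority)
            return (node.var, round(node.threshold, 12),
                    rec(node.left), rec(node.right))
        return rec(self.root)


def _weighted_impurity_curve(n0L, n1L, n0R, n1R, impurity: Callable) -> np.ndarray:
    """nL*I(L) + nR*I(R) for whole candidate-split arrays at once."""
    nL = n0L + n1L
    nR = n0R + n1R
    if impurity is gini_impurity:
        return (nL - (n0L**2 + n1L**2) / nL) + (nR - (n0R**2 + n1R**2) / nR)
    if impurity is entropy_impurity:
        def h(c, tot):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = c * np.log(c / tot)
            return np.where(c > 0, t, 0.0)
        return -(h(n0L, nL) + h(n1L, nL) + h(n0R, nR) + h(n1R, nR))
    return np.array([kL * impurity((a, b)) + kR * impurity((c, d))
                     for a, b, c, d, kL, kR
                     in zip(n0L, n1L, n0R, n1R, nL, nR)])


def best_split(X: np.ndarray, y: np.ndarray, impurity: Callable,
               min_leaf: int) -> tuple[int, float, float] | None:
    """Exhaustive best (variable, threshold) by weighted impurity decrease.

    Returns (var, threshold, decrease) or None when no admissible split
    exists.  Decrease is on the count scale: n*I(parent) - nL*I(L) - nR*I(R).
    Ties keep the lowest variable index, then the smallest threshold.
    """
    n = y.size
    parent = impurity(np.bincount(y, minlength=2)) * n
    n1 = int(y.sum())
    best = None
    for v in range(X.shape[1]):
        order = np.argsort(X[:, v], kind="stable")
        xs, ys = X[order, v], y[order]
        cum1 = np.cumsum(ys)
        ks = np.arange(min_leaf, n - min_leaf + 1)
        if ks.size == 0:
            continue
        ks = ks[xs[ks - 1] < xs[ks]]
        if ks.size == 0:
            continue
        n1L = cum1[ks - 1].astype(float)
        n0L = ks - n1L
        n1R = n1 - n1L
        n0R = (n - ks) - n1R
        dec = parent - _weighted_impurity_curve(n0L, n1L, n0R, n1R, impurity)
        i = int(np.argmax(dec))  # first max -> smallest threshold
        if best is None or dec[i] > best[2] + 1e-12:
            k = ks[i]
            best = (v, (xs[k - 1] + xs[k]) / 2.0, float(dec[i]))
    if best is None or best[2] <= 1e-12:
        return None
    return best


def grow_cart(X: np.ndarray, y: np.ndarray, impurity: str | Callable = "gini",
              min_split: int = 20, min_leaf: int = 7) -> CartTree:
    """Greedy growth until no node can split (purity or size limits)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if y.size == 0:
        raise ValueError("data must be non-empty")
    imp = IMPURITIES[impurity] if isinstance(impurity, str) else impurity

    def rec(idx: np.ndarray, depth: int) -> CartNode:
        counts = np.bincount(y[idx], minlength=2)
        node = CartNode(depth, (int(counts[0]), int(counts[1])))
        if idx.size < min_split or counts.min() == 0:
            return node
        found = best_split(X[idx], y[idx], imp, min_leaf)
        if found is None:
            return node
        node.var, node.threshold, _ = found
        mask = X[idx, node.var] <= node.threshold
        node.left = rec(idx[mask], depth + 1)
        node.right = rec(idx[~mask], depth + 1)
        return node

    return CartTree(rec(np.arange(y.size), 0), y.size)


@dataclass
class PrunedSequence:
    """Nested weakest-link subtrees with strictly increasing complexity."""

    alphas: list[float]
    trees: list[CartTree]

    def __len__(self) -> int:
        return len(self.trees)

    def subtree_for_alpha(self, alpha: float) -> CartTree:
        """Optimal subtree for complexity penalty ``alpha``."""
        i = 0
        for j, a in enumerate(self.alphas):
            if a <= alpha + 1e-12:
                i = j
        return self.trees[i]


def _branch_stats(node: CartNode) -> tuple[int, int]:
    """(misclassified in branch leaves, number of branch leaves)."""
    if node.is_leaf:
        return node.misclassified, 1
    ml, ll = _branch_stats(node.left)
    mr, lr = _branch_stats(node.right)
    return ml + mr, ll + lr


def cost_complexity_prune(tree: CartTree) -> PrunedSequence:
    """Weakest-link pruning.

    Repeatedly collapses the internal node(s) with the smallest
    g = (R(node) - R(branch)) / (leaves(branch) - 1), where R is the
    resubstitution risk contribution on the training-set scale.  The first
    element is the alpha = 0 optimum — the full tree, unless it carries
    branches with zero risk improvement, which any positive penalty prunes
    — and the last is the root-only tree; each entry is the cost-complexity
    optimal subtree on [alpha_k, alpha_{k+1}).
    """
    n = tree.n_train
    current = tree.copy()
    alphas = [0.0]
    trees = [current.copy()]
    while not current.root.is_leaf:
        gs = []
        for node in current.internal_nodes():
            mis_branch, n_leaves = _branch_stats(node)
            g = (node.misclassified - mis_branch) / n / (n_leaves - 1)
            gs.append((g, node))
        gmin = min(g for g, _ in gs)
        for g, node in gs:
            if g <= gmin + 1e-12:
                node.var, node.threshold = None, None
                node.left, node.right = None, None
        # collapsing can orphan other flagged nodes; internal_nodes() above
        # was snapshot before collapse, so re-derive the tree copy now
        snapshot = current.copy()
        if gmin <= alphas[-1] + 1e-12:
            trees[-1] = snapshot
        else:
            alphas.append(gmin)
            trees.append(snapshot)
    return PrunedSequence(alphas=alphas, trees=trees)


def stratified_folds(y: np.ndarray, folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-class round-robin fold assignment after a seeded shuffle."""
    y = np.asarray(y)
    assign = np.empty(y.size, dtype=np.intp)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < folds:
            raise ValueError(f"folds={folds} exceeds class-{cls} count {idx.size}")
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def select_subtree_cv(X: np.ndarray, y: np.ndarray,
                      impurity: str | Callable = "gini", folds: int = 10,
                      seed: int = 0, min_split: int = 20,
                      min_leaf: int = 7) -> CartTree:
    """Grow, prune, and pick the subtree with minimum CV misclassification.

    The main tree's complexity sequence supplies the candidate penalties
    (geometric means of consecutive alphas, as in classic CART); each fold
    grows and prunes its own tree and is evaluated on the held-out part.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    counts = np.bincount(y, minlength=2)
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds minority class count "
                         f"{int(counts.min())}")
    full = grow_cart(X, y, impurity, min_split, min_leaf)
    seq = cost_complexity_prune(full)
    if len(seq) == 1:
        return seq.trees[0]
    alphas = np.asarray(seq.alphas)
    mids = np.sqrt(alphas[:-1] * np.maximum(alphas[1:], 0.0))
    cand_alphas = np.concatenate([mids, [alphas[-1]]])
    rng = np.random.default_rng(seed)
    assign = stratified_folds(y, folds, rng)
    errors = np.zeros(cand_alphas.size)
    for f in range(folds):
        tr, te = assign != f, assign == f
        fold_tree = grow_cart(X[tr], y[tr], impurity, min_split, min_leaf)
        fold_seq = cost_complexity_prune(fold_tree)
        for j, a in enumerate(cand_alphas):
            sub = fold_seq.subtree_for_alpha(a)
            pred = predict_cart(sub, X[te])
            errors[j] += int(np.sum(pred != y[te]))
    # minimum CV error; ties resolve to the smaller tree (larger alpha)
    best_j = max(np.flatnonzero(errors == errors.min()))
    return seq.subtree_for_alpha(cand_alphas[best_j])


def predict_cart(tree: CartTree, X: np.ndarray) -> np.ndarray:
    """Majority label of the routed terminal node."""
    return np.array([n.majority for n in tree.route(X)], dtype=np.int8)


def leaf_scores(tree: CartTree, X: np.ndarray) -> np.ndarray:
    """Training-estimated P(class 1) of each sample's terminal node."""
    return np.array([n.counts[1] / n.n for n in tree.route(X)])
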