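"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own computational paths:
tree spaces are enumerated exhaustively, marginal likelihoods are computed
by adaptive quadrature, CART splits/subtrees by brute force, and AUCs by
explicit pairwise concordance counting.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.special import expit

from hemtree.tree_core import (Node, SplitRule, TreeModel,
                               admissible_split_map)


# ---------------------------------------------------------------------------
# Exhaustive tree-space enumeration
# ---------------------------------------------------------------------------

def enumerate_trees(X: np.ndarray, min_node_size: int) -> list[TreeModel]:
    """All admissible trees on the dataset (finite for tiny toys)."""

    def rec(idx: np.ndarray, depth: int) -> list[Node]:
        splits = admissible_split_map(X, idx, min_node_size)
        out = [Node(depth)]
        for v in sorted(splits):
            for t in splits[v]:
                mask = X[idx, v] <= t
                lefts = rec(idx[mask], depth + 1)
                rights = rec(idx[~mask], depth + 1)
                for left in lefts:
                    for right in rights:
                        out.append(Node(depth, SplitRule(v, float(t)),
                                        left.copy(), right.copy()))
        return out

    return [TreeModel(r) for r in rec(np.arange(X.shape[0]), 0)]


def chain_visit_frequencies(X, keys, step_fn, n_steps: int, thin: int = 5):
    """Visit frequency of each canonical key along a thinned chain.

    ``step_fn()`` advances the chain one transition and returns the current
    tree.  Returns (frequencies aligned with keys, number of thinned draws).
    """
    counts = {k: 0 for k in keys}
    kept = 0
    for i in range(n_steps):
        tree = step_fn()
        if i % thin == 0:
            counts[tree.canonical_key(X)] += 1
            kept += 1
    return np.array([counts[k] / kept for k in keys]), kept


# ---------------------------------------------------------------------------
# Quadrature for the node marginal likelihood
# ---------------------------------------------------------------------------

def _log_integrand(b, X1, y, prior_sd):
    eta = X1 @ b
    return (np.sum(y * eta - np.logaddexp(0.0, eta))
            - 0.5 * b.size * np.log(2 * np.pi * prior_sd**2)
            - 0.5 * np.dot(b, b) / prior_sd**2)


def quadrature_log_marginal(X, y, prior_sd) -> float:
    """Adaptive quadrature of the exact node integral (1 or 2 coefficients).

    Integration is centered on the posterior mode with a generous window of
    +/- 12 posterior standard deviations (mode/curvature located by a short
    independent Newton run on the integrand itself).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X1 = np.hstack([np.ones((X.shape[0], 1)), X])
    y = np.asarray(y, dtype=float)
    p = X1.shape[1]
    if p > 2:
        raise ValueError("quadrature oracle supports 1-2 coefficients")
    # crude mode/curvature hunt (independent of the package fit routine)
    b = np.zeros(p)
    for _ in range(200):
        mu = expit(X1 @ b)
        g = X1.T @ (y - mu) - b / prior_sd**2
        H = X1.T @ (X1 * (mu * (1 - mu))[:, None]) + np.eye(p) / prior_sd**2
        step = np.linalg.solve(H, g)
        b = b + np.clip(step, -1.0, 1.0)
        if np.max(np.abs(g)) < 1e-10:
            break
    sd = np.sqrt(np.diag(np.linalg.inv(H)))
    lo, hi = b - 12 * sd, b + 12 * sd
    peak = _log_integrand(b, X1, y, prior_sd)
    if p == 1:
        val, _ = integrate.quad(
            lambda t: math.exp(_log_integrand(np.array([t]), X1, y, prior_sd)
                               - peak),
            lo[0], hi[0], limit=200)
    else:
        val, _ = integrate.dblquad(
            lambda t1, t0: math.exp(
                _log_integrand(np.array([t0, t1]), X1, y, prior_sd) - peak),
            lo[0], hi[0], lo[1], hi[1], epsabs=1e-10)
    return peak + math.log(val)


# ---------------------------------------------------------------------------
# CART brute force
# ---------------------------------------------------------------------------

def brute_force_best_split(X, y, impurity, min_leaf):
    """Exhaustive (variable, threshold) search by direct evaluation."""
    n = y.size
    parent = impurity(np.bincount(y, minlength=2)) * n
    best = None
    for v in range(X.shape[1]):
        values = np.unique(X[:, v])
        for a, b in zip(values[:-1], values[1:]):
            t = (a + b) / 2.0
            left = X[:, v] <= t
            nl, nr = int(left.sum()), int(n - left.sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            dec = (parent
                   - nl * impurity(np.bincount(y[left], minlength=2))
                   - nr * impurity(np.bincount(y[~left], minlength=2)))
            if best is None or dec > best[2] + 1e-12:
                best = (v, t, dec)
    if best is None or best[2] <= 1e-12:
        return None
    return best


def all_pruned_subtrees(tree):
    """Every subtree obtainable by collapsing internal nodes (as structure
    tuples) together with (misclassified count, n_leaves)."""

    def rec(node):
        # returns list of (structure, misclassified, leaves)
        leaf_version = (("leaf", node.majority), min(node.counts), 1)
        if node.is_leaf:
            return [leaf_version]
        out = [leaf_version]
        for (ls, lm, ll) in rec(node.left):
            for (rs, rm, rl) in rec(node.right):
                out.append(((node.var, round(node.threshold, 12), ls, rs),
                            lm + rm, ll + rl))
        return out

    return rec(tree.root)


def optimal_subtree_cost(tree, alpha):
    """min over pruned subtrees of R(T) + alpha * |leaves(T)|."""
    n = tree.n_train
    return min(m / n + alpha * l for _, m, l in all_pruned_subtrees(tree))


# ---------------------------------------------------------------------------
# AUC by explicit concordance
# ---------------------------------------------------------------------------

def concordance_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)
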