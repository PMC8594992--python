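"""Binary-tree representation, split semantics and the tree-generating prior.

A classification tree over the four hematological predictors (MCV, MCH, Hb,
RDW) is a binary tree whose internal nodes carry threshold split rules
("value <= threshold" routes left, "> threshold" routes right) and whose
terminal nodes may carry a per-node logistic model.

The prior over tree structures is the recursive stochastic process of
Chipman-style Bayesian CART: a node at depth ``d`` splits with probability

    P(split) = alpha * (1 + d) ** (-beta),

and, conditional on splitting, the rule is drawn uniformly over predictors
that admit a split and then uniformly over the admissible thresholds of the
chosen predictor.  Admissible thresholds are identified with the *gaps*
between consecutive distinct observed values of a predictor within the node
that leave at least ``min_node_size`` samples on each side; the canonical
numeric threshold of a gap is its midpoint.  A node with no admissible split
is terminal with probability one and contributes no non-split factor to the
prior, which makes the prior a proper (normalized) distribution over the
finite space of admissible trees for a given training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

PREDICTORS: tuple[str, ...] = ("mcv", "mch", "hb", "rdw")
LABEL_COLUMN = "label"

__all__ = [
    "PREDICTORS",
    "LABEL_COLUMN",
    "SplitRule",
    "TreePriorParams",
    "Node",
    "TreeModel",
    "InvalidTreeError",
    "split_probability",
    "admissible_thresholds",
    "admissible_split_map",
    "sample_tree_from_prior",
    "log_tree_prior",
    "partition",
    "read_cohort",
    "write_cohort",
    "tree_to_dict",
    "tree_from_dict",
]


class InvalidTreeError(ValueError):
    """A tree whose rules are inadmissible for the data it is applied to."""


@dataclass(frozen=True)
class SplitRule:
    """Axis-aligned threshold rule: ``x[var] <= threshold`` goes left."""

    var: int
    threshold: float

    @property
    def var_name(self) -> str:
        return PREDICTORS[self.var]


@dataclass(frozen=True)
class TreePriorParams:
    """(alpha, beta) of the depth-penalized split probability."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


class Node:
    """One tree node; internal iff ``rule`` is not None."""

    __slots__ = ("depth", "rule", "left", "right", "model")

    def __init__(self, depth: int, rule: SplitRule | None = None,
                 left: "Node | None" = None, right: "Node | None" = None,
                 model=None):
        self.depth = depth
        self.rule = rule
        self.left = left
        self.right = right
        self.model = model

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    def copy(self) -> "Node":
        return Node(
            self.depth,
            self.rule,
            self.left.copy() if self.left is not None else None,
            self.right.copy() if self.right is not None else None,
            self.model,
        )


class TreeModel:
    """Binary decision tree with threshold splits and optional leaf models."""

    def __init__(self, root: Node):
        self.root = root

    # -- structure ---------------------------------------------------------
    def copy(self) -> "TreeModel":
        return TreeModel(self.root.copy())

    def nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def n_internal(self) -> int:
        return len(self.internal_nodes())

    @property
    def max_depth(self) -> int:
        return max(n.depth for n in self.nodes())

    # -- data routing ------------------------------------------------------
    def leaf_assignment(self, X: np.ndarray) -> np.ndarray:
        """Index (preorder over leaves) of the terminal node of each row."""
        X = _check_predictor_matrix(X)
        out = np.empty(X.shape[0], dtype=np.intp)
        leaf_counter = [0]

        def rec(node: Node, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = leaf_counter[0]
                leaf_counter[0] += 1
                return
            mask = X[idx, node.rule.var] <= node.rule.threshold
            rec(node.left, idx[mask])
            rec(node.right, idx[~mask])

        rec(self.root, np.arange(X.shape[0]))
        return out

    def leaf_blocks(self, X: np.ndarray) -> list[np.ndarray]:
        """Row-index block of each terminal node, in preorder leaf order."""
        X = _check_predictor_matrix(X)
        blocks: list[np.ndarray] = []

        def rec(node: Node, idx: np.ndarray) -> None:
            if node.is_leaf:
                blocks.append(idx)
                return
            mask = X[idx, node.rule.var] <= node.rule.threshold
            rec(node.left, idx[mask])
            rec(node.right, idx[~mask])

        rec(self.root, np.arange(X.shape[0]))
        return blocks

    def canonical_key(self, X: np.ndarray):
        """Hashable identity of the partition the tree induces on ``X``.

        Thresholds are identified by the data gap they fall in, so two trees
        whose thresholds differ but induce identical recursive partitions
        share a key.  Used by the enumeration oracles in the test suite.
        """
        X = _check_predictor_matrix(X)

        def rec(node: Node, idx: np.ndarray):
            if node.is_leaf:
                return "leaf"
            x = X[idx, node.rule.var]
            k = int(np.sum(x <= node.rule.threshold))
            mask = X[idx, node.rule.var] <= node.rule.threshold
            return (node.rule.var, k, rec(node.left, idx[mask]),
                    rec(node.right, idx[~mask]))

        return rec(self.root, np.arange(X.shape[0]))


def _check_predictor_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("predictor matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictor matrix contains missing/non-finite values")
    return X


# ---------------------------------------------------------------------------
# Tree prior
# ---------------------------------------------------------------------------

def split_probability(depth: int, params: TreePriorParams) -> float:
    """Probability that a node at ``depth`` splits: alpha*(1+depth)**(-beta)."""
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    return params.alpha * (1.0 + depth) ** (-params.beta)


def admissible_thresholds(x: np.ndarray, min_node_size: int) -> np.ndarray:
    """Canonical thresholds (gap midpoints) splitting ``x`` admissibly.

    A gap between consecutive distinct sorted values is admissible when both
    sides of the induced split hold at least ``min_node_size`` points.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * min_node_size:
        return np.empty(0)
    xs = np.sort(x)
    ks = np.arange(min_node_size, n - min_node_size + 1)
    mask = xs[ks - 1] < xs[ks]
    return (xs[ks - 1][mask] + xs[ks][mask]) / 2.0


def admissible_split_map(X: np.ndarray, idx: np.ndarray,
                         min_node_size: int) -> dict[int, np.ndarray]:
    """Per-predictor admissible thresholds within the node block ``idx``."""
    out: dict[int, np.ndarray] = {}
    for v in range(X.shape[1]):
        ts = admissible_thresholds(X[idx, v], min_node_size)
        if ts.size:
            out[v] = ts
    return out


def threshold_gap(x: np.ndarray, threshold: float,
                  min_node_size: int) -> int | None:
    """Left-side count of the admissible gap containing ``threshold``.

    Returns None when the threshold does not lie strictly between two
    distinct observed values with both sides >= min_node_size.
    """
    x = np.asarray(x, dtype=float)
    k = int(np.sum(x <= threshold))
    if k < min_node_size or x.size - k < min_node_size:
        return None
    xs = np.sort(x)
    if not (xs[k - 1] < threshold < xs[k]):
        return None
    return k


def sample_tree_from_prior(X: np.ndarray, params: TreePriorParams,
                           min_node_size: int,
                           rng: np.random.Generator | int) -> TreeModel:
    """Draw one tree from the generating process on the given training data."""
    X = _check_predictor_matrix(X)
    if X.shape[0] == 0:
        raise ValueError("data must be non-empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    def rec(idx: np.ndarray, depth: int) -> Node:
        splits = admissible_split_map(X, idx, min_node_size)
        if not splits or rng.random() >= split_probability(depth, params):
            return Node(depth)
        var = int(sorted(splits)[rng.integers(len(splits))])
        ts = splits[var]
        threshold = float(ts[rng.integers(ts.size)])
        mask = X[idx, var] <= threshold
        node = Node(depth, SplitRule(var, threshold))
        node.left = rec(idx[mask], depth + 1)
        node.right = rec(idx[~mask], depth + 1)
        return node

    return TreeModel(rec(np.arange(X.shape[0]), 0))


def log_tree_prior(tree: TreeModel, params: TreePriorParams, X: np.ndarray,
                   min_node_size: int) -> float:
    """Log prior probability of the tree under the generating process.

    Internal nodes contribute log P(split) plus the log of the uniform rule
    probability (1 / #splittable predictors * 1 / #admissible gaps); terminal
    nodes contribute log(1 - P(split)) unless no admissible split exists, in
    which case they contribute 0.
    """
    X = _check_predictor_matrix(X)

    def rec(node: Node, idx: np.ndarray) -> float:
        splits = admissible_split_map(X, idx, min_node_size)
        p_split = split_probability(node.depth, params)
        if node.is_leaf:
            return float(np.log1p(-p_split)) if splits else 0.0
        if not splits:
            raise InvalidTreeError("internal node with no admissible split")
        rule = node.rule
        if rule.var not in splits:
            raise InvalidTreeError(
                f"no admissible threshold for predictor {rule.var_name}")
        if threshold_gap(X[idx, rule.var], rule.threshold, min_node_size) is None:
            raise InvalidTreeError(
                f"threshold {rule.threshold} inadmissible for {rule.var_name}")
        lp = (np.log(p_split) - np.log(len(splits))
              - np.log(splits[rule.var].size))
        mask = X[idx, rule.var] <= rule.threshold
        return float(lp + rec(node.left, idx[mask]) + rec(node.right, idx[~mask]))

    return rec(tree.root, np.arange(X.shape[0]))


def partition(tree: TreeModel, X: np.ndarray) -> np.ndarray:
    """Terminal-node index of every sample (exhaustive, mutually exclusive)."""
    return tree.leaf_assignment(X)


# ---------------------------------------------------------------------------
# Dataset I/O (shared CSV dialect: header mcv,mch,hb,rdw,label)
# ---------------------------------------------------------------------------

def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = list(PREDICTORS) + [LABEL_COLUMN]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    df = df[expected].copy()
    validate_cohort(df)
    return df

def write_cohort(df: pd.DataFrame, path) -> None:
    validate_cohort(df)
    df[list(PREDICTORS) + [LABEL_COLUMN]].to_csv(path, index=False)


def validate_cohort(df: pd.DataFrame) -> None:
    values = df[list(PREDICTORS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("predictors must be strictly positive and finite")
    labels = df[LABEL_COLUMN].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 (IDA) or 1 (bTT)")


def cohort_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with predictor columns in canonical order."""
    X = df[list(PREDICTORS)].to_numpy(dtype=float)
    y = df[LABEL_COLUMN].to_numpy(dtype=np.int8)
    return X, y


# ---------------------------------------------------------------------------
# Serialization (machine-readable nested dict; JSON-compatible)
# ---------------------------------------------------------------------------

def tree_to_dict(tree: TreeModel, standardization=None) -> dict:
    def rec(node: Node, node_id: list[int]) -> dict:
        nid = node_id[0]
        node_id[0] += 1
        d: dict = {"id": nid, "depth": node.depth}
        if node.is_leaf:
            d["leaf"] = True
            if node.model is not None:
                d["coefficients"] = [float(c) for c in node.model.coefficients]
                d["prior_sd"] = float(node.model.prior_sd)
        else:
            d["leaf"] = False
            d["rule"] = {"var": node.rule.var_name,
                         "threshold": float(node.rule.threshold)}
            d["left"] = rec(node.left, node_id)
            d["right"] = rec(node.right, node_id)
        return d

    out = {"tree": rec(tree.root, [0])}
    if standardization is not None:
        out["standardization"] = {
            "mean": [float(m) for m in standardization.mean],
            "scale": [float(s) for s in standardization.scale],
            "columns": list(standardization.columns),
        }
    return out


def tree_from_dict(d: dict) -> TreeModel:
    from .node_model import NodeLogisticModel  # cycle-free at call time

    def rec(nd: dict) -> Node:
        if nd["leaf"]:
            node = Node(int(nd["depth"]))
            if "coefficients" in nd:
                node.model = NodeLogisticModel(
                    coefficients=np.asarray(nd["coefficients"], dtype=float),
                    prior_sd=float(nd.get("prior_sd", 20.0)))
            return node
        rule = SplitRule(PREDICTORS.index(nd["rule"]["var"]),
                         float(nd["rule"]["threshold"]))
        return Node(int(nd["depth"]), rule, rec(nd["left"]), rec(nd["right"]))

    return TreeModel(rec(d["tree"]))


def save_tree(tree: TreeModel, path, standardization=None) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree, standardization), fh, indent=2)


def load_tree(path) -> TreeModel:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))
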