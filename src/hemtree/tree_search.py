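"""Metropolis-Hastings stochastic search over tree space.

The posterior over trees, P(T | X, y) proportional to p(y | X, T) p(T), is
explored with the four classic structural proposals:

* GROW   -- split a uniformly chosen growable terminal node with a rule
            drawn uniformly over admissible predictors and thresholds;
* PRUNE  -- collapse a uniformly chosen internal node whose children are
            both terminal;
* CHANGE -- redraw the rule of a uniformly chosen internal node;
* SWAP   -- swap the rules of a uniformly chosen parent-child internal pair.

Acceptance uses min(1, exp(delta log marginal + delta log prior + log
proposal ratio)); candidates that leave any terminal node below
``min_node_size`` or carry an inadmissible rule downstream are rejected
outright.  Chains start from the root-only tree and are restarted several
times from independent sub-streams of the master seed; the search result is
the visited tree maximizing log marginal + log prior, per restart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .node_model import (NodeFitError, StandardizationParams, fit_node_map,
                         log_marginal_node, predict_node)
from .tree_core import (InvalidTreeError, Node, SplitRule, TreeModel,
                        TreePriorParams, admissible_split_map, log_tree_prior,
                        threshold_gap)

MOVES = ("grow", "prune", "change", "swap")

__all__ = [
    "SearchConfig",
    "SearchTrace",
    "TreeScorer",
    "propose_move",
    "mh_step",
    "run_search",
    "hyperparameter_sweep",
    "fit_tree_models",
    "classify",
]


@dataclass(frozen=True)
class SearchConfig:
    """Chain settings; defaults are the study configuration."""

    restarts: int = 8
    iterations: int = 6000
    move_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.4, 0.1)
    min_node_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1 or self.iterations < 1:
            raise ValueError("restarts and iterations must be >= 1")
        p = np.asarray(self.move_probs, dtype=float)
        if p.size != 4 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("move_probs must be 4 non-negative values summing to 1")


@dataclass
class SearchTrace:
    """Per-iteration chain record plus per-restart best trees."""

    records: list[tuple] = field(default_factory=list)
    best_trees: list[TreeModel] = field(default_factory=list)
    best_scores: list[float] = field(default_factory=list)

    COLUMNS = ("restart", "iteration", "log_marginal", "log_prior",
               "n_leaves", "accepted")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=self.COLUMNS)

    def export_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def best_tree(self) -> TreeModel:
        i = int(np.argmax(self.best_scores))
        return self.best_trees[i]

    @property
    def best_score(self) -> float:
        return float(np.max(self.best_scores))


class TreeScorer:
    """Caches per-leaf Laplace marginals; scores trees on one training set."""

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 prior_params: TreePriorParams, prior_sd: float,
                 min_node_size: int):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.prior_params = prior_params
        self.prior_sd = prior_sd
        self.min_node_size = min_node_size
        self._memo: dict[bytes, float] = {}

    def node_marginal(self, idx: np.ndarray) -> float:
        key = idx.tobytes()
        v = self._memo.get(key)
        if v is None:
            v = log_marginal_node(self.X[idx], self.y[idx], self.prior_sd)
            self._memo[key] = v
        return v

    def log_marginal(self, tree: TreeModel) -> float:
        total = 0.0
        for idx in tree.leaf_blocks(self.X):
            if idx.size < self.min_node_size:
                raise NodeFitError("leaf below min_node_size")
            total += self.node_marginal(idx)
        return total

    def log_prior(self, tree: TreeModel) -> float:
        return log_tree_prior(tree, self.prior_params, self.X,
                              self.min_node_size)

    def score(self, tree: TreeModel) -> tuple[float, float]:
        return self.log_marginal(tree), self.log_prior(tree)


class PriorOnlyScorer(TreeScorer):
    """Scorer with the likelihood disabled (log marginal identically 0).

    Makes the chain's stationary distribution the tree prior itself; used
    for analytic validation of the sampler.
    """

    def log_marginal(self, tree: TreeModel) -> float:
        for idx in tree.leaf_blocks(self.X):
            if idx.size < self.min_node_size:
                raise NodeFitError("leaf below min_node_size")
        return 0.0


# ---------------------------------------------------------------------------
# Structural proposals
# ---------------------------------------------------------------------------

def _node_blocks(tree: TreeModel, X: np.ndarray) -> dict[int, np.ndarray]:
    blocks: dict[int, np.ndarray] = {}

    def rec(node: Node, idx: np.ndarray) -> None:
        blocks[id(node)] = idx
        if not node.is_leaf:
            mask = X[idx, node.rule.var] <= node.rule.threshold
            rec(node.left, idx[mask])
            rec(node.right, idx[~mask])

    rec(tree.root, np.arange(X.shape[0]))
    return blocks


def _subtree_valid(node: Node, X: np.ndarray, idx: np.ndarray,
                   min_node_size: int) -> bool:
    if node.is_leaf:
        return idx.size >= min_node_size
    if threshold_gap(X[idx, node.rule.var], node.rule.threshold,
                     min_node_size) is None:
        return False
    mask = X[idx, node.rule.var] <= node.rule.threshold
    return (_subtree_valid(node.left, X, idx[mask], min_node_size)
            and _subtree_valid(node.right, X, idx[~mask], min_node_size))


def _draw_rule(splits: dict[int, np.ndarray], rng) -> tuple[SplitRule, int, int]:
    """Uniform (predictor, gap-midpoint) draw; returns rule and counts."""
    variables = sorted(splits)
    var = variables[rng.integers(len(variables))]
    ts = splits[var]
    t = float(ts[rng.integers(ts.size)])
    return SplitRule(var, t), len(variables), ts.size


def _grow_choices(tree: TreeModel, blocks, X, min_node_size):
    out = []
    for leaf in tree.leaves():
        splits = admissible_split_map(X, blocks[id(leaf)], min_node_size)
        if splits:
            out.append((leaf, splits))
    return out


def _prunable(tree: TreeModel) -> list[Node]:
    return [n for n in tree.internal_nodes()
            if n.left.is_leaf and n.right.is_leaf]


def propose_move(tree: TreeModel, X: np.ndarray, min_node_size: int,
                 move_probs, rng: np.random.Generator):
    """One structural proposal.

    Returns (candidate, log_q_ratio, move_name).  The candidate is None when
    the proposal is invalid (to be rejected outright); an inapplicable move
    returns the unchanged tree with ratio 0.
    """
    p = np.asarray(move_probs, dtype=float)
    move = MOVES[rng.choice(4, p=p)]
    cand = tree.copy()
    blocks = _node_blocks(cand, X)
    log_p = {m: np.log(p[i]) if p[i] > 0 else -np.inf
             for i, m in enumerate(MOVES)}

    if move == "grow":
        choices = _grow_choices(cand, blocks, X, min_node_size)
        if not choices:
            return tree, 0.0, move
        leaf, splits = choices[rng.integers(len(choices))]
        rule, n_vars, n_ts = _draw_rule(splits, rng)
        leaf.rule = rule
        leaf.left = Node(leaf.depth + 1)
        leaf.right = Node(leaf.depth + 1)
        leaf.model = None
        log_fwd = log_p["grow"] - np.log(len(choices)) - np.log(n_vars) - np.log(n_ts)
        log_rev = log_p["prune"] - np.log(len(_prunable(cand)))
        return cand, float(log_rev - log_fwd), move

    if move == "prune":
        prunable = _prunable(cand)
        if not prunable:
            return tree, 0.0, move
        node = prunable[rng.integers(len(prunable))]
        old_rule = node.rule
        idx = blocks[id(node)]
        node.rule, node.left, node.right = None, None, None
        splits = admissible_split_map(X, idx, min_node_size)
        log_fwd = log_p["prune"] - np.log(len(prunable))
        n_grow = len(_grow_choices(cand, _node_blocks(cand, X), X, min_node_size))
        log_rev = (log_p["grow"] - np.log(n_grow) - np.log(len(splits))
                   - np.log(splits[old_rule.var].size))
        return cand, float(log_rev - log_fwd), move

    if move == "change":
        internal = cand.internal_nodes()
        if not internal:
            return tree, 0.0, move
        node = internal[rng.integers(len(internal))]
        idx = blocks[id(node)]
        splits = admissible_split_map(X, idx, min_node_size)
        old_rule = node.rule
        new_rule, _, _ = _draw_rule(splits, rng)
        node.rule = new_rule
        if not _subtree_valid(node, X, idx, min_node_size):
            return None, -np.inf, move
        # node block is unchanged, so selection counts cancel except the
        # per-variable gap counts of the old vs new rule
        log_q = float(np.log(splits[new_rule.var].size)
                      - np.log(splits[old_rule.var].size))
        return cand, log_q, move

    # swap
    pairs = [(n, c) for n in cand.internal_nodes()
             for c in (n.left, n.right) if not c.is_leaf]
    if not pairs:
        return tree, 0.0, move
    parent, child = pairs[rng.integers(len(pairs))]
    parent.rule, child.rule = child.rule, parent.rule
    if not _subtree_valid(parent, X, blocks[id(parent)], min_node_size):
        return None, -np.inf, move
    return cand, 0.0, move


def mh_step(tree: TreeModel, scorer: TreeScorer, move_probs,
            rng: np.random.Generator,
            current_score: tuple[float, float] | None = None):
    """One Metropolis-Hastings transition.

    Returns (tree, accepted, (log_marginal, log_prior)).
    """
    if current_score is None:
        current_score = scorer.score(tree)
    cand, log_q, _move = propose_move(tree, scorer.X, scorer.min_node_size,
                                      move_probs, rng)
    if cand is None:
        rng.random()  # keep stream usage regular for rejected proposals
        return tree, False, current_score
    if cand is tree:  # inapplicable move: proposal equals current state
        rng.random()
        return tree, True, current_score
    try:
        cand_score = scorer.score(cand)
    except (NodeFitError, InvalidTreeError):
        rng.random()
        return tree, False, current_score
    log_alpha = (cand_score[0] + cand_score[1]
                 - current_score[0] - current_score[1] + log_q)
    if np.log(rng.random()) < min(0.0, log_alpha):
        return cand, True, cand_score
    return tree, False, current_score


def run_search(X: np.ndarray, y: np.ndarray, prior_params: TreePriorParams,
               prior_sd: float, config: SearchConfig,
               scorer: TreeScorer | None = None) -> SearchTrace:
    """Multiple independent restarts of the MH chain from the root-only tree."""
    if scorer is None:
        scorer = TreeScorer(X, y, prior_params, prior_sd, config.min_node_size)
    trace = SearchTrace()
    for r in range(config.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        tree = TreeModel(Node(0))
        score = scorer.score(tree)
        best_tree, best = tree, sum(score)
        for it in range(config.iterations):
            tree, accepted, score = mh_step(tree, scorer, config.move_probs,
                                            rng, score)
            total = score[0] + score[1]
            if total > best:
                best, best_tree = total, tree
            trace.records.append((r, it, score[0], score[1],
                                  tree.n_leaves, accepted))
        trace.best_trees.append(best_tree.copy())
        trace.best_scores.append(best)
    return trace


# ---------------------------------------------------------------------------
# Prediction and hyperparameter selection
# ---------------------------------------------------------------------------

def fit_tree_models(tree: TreeModel, X: np.ndarray, y: np.ndarray,
                    prior_sd: float) -> TreeModel:
    """Attach MAP logistic models to every terminal node (in place)."""
    y = np.asarray(y)
    leaves = tree.leaves()
    for leaf, idx in zip(leaves, tree.leaf_blocks(X)):
        leaf.model = fit_node_map(X[idx], y[idx], prior_sd)
    return tree


def classify(tree: TreeModel, std: StandardizationParams, data,
             threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in posterior-predictive classification.

    Routes each sample (standardized with the *training* params) to its
    terminal node and evaluates that node's MAP logistic probability; labels
    bTT (1) when the probability is >= threshold.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if isinstance(data, pd.DataFrame):
        from .tree_core import cohort_arrays
        X = cohort_arrays(data)[0]
    else:
        X = np.asarray(data, dtype=float)
    Z = std.transform(X)
    probs = np.empty(Z.shape[0])
    for leaf, idx in zip(tree.leaves(), tree.leaf_blocks(Z)):
        if leaf.model is None:
            raise ValueError("tree has unfitted terminal nodes")
        if idx.size:
            probs[idx] = predict_node(leaf.model, Z[idx])
    labels = (probs >= threshold).astype(np.int8)
    return labels, probs


@dataclass
class SweepResult:
    params: TreePriorParams
    tree: TreeModel
    fnr: float
    table: pd.DataFrame
    trace: SearchTrace


def hyperparameter_sweep(X: np.ndarray, y: np.ndarray, std: StandardizationParams,
                         prior_sd: float, config: SearchConfig,
                         alphas=(0.5, 0.95), betas=(0.5, 1.0, 1.5, 2.0),
                         threshold: float = 0.5) -> SweepResult:
    """Grid search over (alpha, beta); select the pair whose best tree has
    the smallest training false-negative rate.

    Ties break toward higher log marginal + log prior, then fewer leaves.
    ``X`` must already be standardized with ``std``.
    """
    alphas, betas = list(alphas), list(betas)
    if not alphas or not betas:
        raise ValueError("alpha/beta grids must be non-empty")
    y = np.asarray(y)
    n_pos = int(np.sum(y == 1))
    rows, candidates = [], []
    raw = std.inverse_transform(X)
    for a in alphas:
        for b in betas:
            params = TreePriorParams(a, b)
            trace = run_search(X, y, params, prior_sd, config)
            tree = fit_tree_models(tree=trace.best_tree, X=X, y=y,
                                   prior_sd=prior_sd)
            labels, _ = classify(tree, std, raw, threshold)
            fn = int(np.sum((labels == 0) & (y == 1)))
            fnr = fn / n_pos if n_pos else np.nan
            rows.append((a, b, fnr, trace.best_score, tree.n_leaves))
            candidates.append((params, tree, fnr, trace))
    table = pd.DataFrame(rows, columns=["alpha", "beta", "train_fnr",
                                        "best_score", "n_leaves"])
    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates[i][2], -candidates[i][3].best_score,
                                  candidates[i][1].n_leaves))
    params, tree, fnr, trace = candidates[order[0]]
    return SweepResult(params=params, tree=tree, fnr=float(fnr),
                       table=table, trace=trace)
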