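"""End-to-end experiment: cohort -> split -> BLTREED + CART1/CART2 ->
diagnostic-accuracy reports and paired AUC comparisons.

``run_full_analysis`` executes the whole study design on a loaded or
generated cohort: stratified train/test split, training-set
standardization, the (alpha, beta) hyperparameter sweep with
Metropolis-Hastings tree search for the Bayesian logit treed model, Gini-
and entropy-grown cost-complexity-pruned CART with cross-validated subtree
selection, classification of both splits by all three models, the full
metric battery with exact CIs, ROC/AUC with DeLong SEs, and pairwise
DeLong tests on the test split.  The report is reproducible bit-for-bit
from (config, seed) and every metric in it is recomputable from its own
stored confusion counts (``AnalysisReport.audit`` checks this).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cart as cart_mod
from .evaluation import (ConfusionCounts, DelongResult, MetricReport,
                         RocResult, compute_metrics, confusion, roc_auc,
                         delong_test)
from .node_model import StandardizationParams, standardize
from .synthetic_data import CohortSpec, generate_cohort, stratified_split
from .tree_core import (LABEL_COLUMN, PREDICTORS, TreeModel, cohort_arrays,
                        read_cohort, tree_to_dict)
from .tree_search import SearchConfig, classify, hyperparameter_sweep

MODEL_NAMES = ("bltreed", "cart_gini", "cart_entropy")

__all__ = ["RunConfig", "AnalysisReport", "run_full_analysis",
           "render_tree", "parse_rendered_tree"]


@dataclass
class RunConfig:
    """Everything the experiment needs; defaults are the study settings."""

    data_path: str | None = None          # CSV cohort; None -> generate
    cohort_spec: CohortSpec | None = None
    seed: int = 0
    train_fraction: float = 0.7
    search: SearchConfig = field(default_factory=SearchConfig)
    prior_sd: float = 20.0
    alphas: tuple[float, ...] = (0.5, 0.95)
    betas: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    cart_min_split: int = 20
    cart_min_leaf: int = 7
    cart_folds: int = 10
    threshold: float = 0.5

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "train_fraction": self.train_fraction,
            "restarts": self.search.restarts,
            "iterations": self.search.iterations,
            "min_node_size": self.search.min_node_size,
            "prior_sd": self.prior_sd,
            "alphas": list(self.alphas),
            "betas": list(self.betas),
            "cart": {"min_split": self.cart_min_split,
                     "min_leaf": self.cart_min_leaf,
                     "folds": self.cart_folds},
            "threshold": self.threshold,
            "data": self.data_path or "synthetic cohort",
        }


@dataclass
class AnalysisReport:
    config: dict
    selected_prior: tuple[float, float]
    confusions: dict[tuple[str, str], ConfusionCounts]
    metrics: dict[tuple[str, str], MetricReport]
    rocs: dict[tuple[str, str], RocResult]
    delong: dict[tuple[str, str], DelongResult]
    trees: dict[str, object]        # serialized tree structures
    sweep_table: pd.DataFrame

    def audit(self) -> bool:
        """Every reported metric must be recomputable from its counts."""
        for key, rep in self.metrics.items():
            fresh = compute_metrics(rep.counts)
            if fresh.display() != rep.display():
                return False
            if rep.counts != self.confusions[key]:
                return False
        return True

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for (model, ds), rep in sorted(self.metrics.items()):
            disp = rep.display()
            c = rep.counts
            row = {"model": model, "dataset": ds, "tp": c.tp, "fp": c.fp,
                   "fn": c.fn, "tn": c.tn}
            row.update(disp)
            rows.append(row)
        return pd.DataFrame(rows)

    def auc_frame(self) -> pd.DataFrame:
        rows = []
        for (model, ds), roc in sorted(self.rocs.items()):
            rows.append({"model": model, "dataset": ds,
                         "auc": round(roc.auc, 4), "se": round(roc.se, 4),
                         "ci_lo": round(roc.ci[0], 4),
                         "ci_hi": round(roc.ci[1], 4), "band": roc.band})
        return pd.DataFrame(rows)

    def delong_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), res in sorted(self.delong.items()):
            rows.append({"model_a": a, "model_b": b,
                         "auc_a": round(res.auc_a, 4),
                         "auc_b": round(res.auc_b, 4),
                         "difference": round(res.difference, 4),
                         "z": round(res.z, 4),
                         "p_value": round(res.p_value, 4)})
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = ["# Differential-diagnosis analysis report", ""]
        lines.append("## Configuration")
        lines.append(json.dumps(self.config, indent=2, sort_keys=True))
        lines.append("")
        a, b = self.selected_prior
        lines.append(f"Selected tree-prior hyperparameters: "
                     f"alpha={a:g}, beta={b:g}")
        lines.append("")
        lines.append("## Diagnostic accuracy (point estimate (95% CI))")
        lines.append(self.metrics_frame().to_string(index=False))
        lines.append("")
        lines.append("## AUC (DeLong SE)")
        lines.append(self.auc_frame().to_string(index=False))
        lines.append("")
        lines.append("## Pairwise DeLong comparisons (test split)")
        lines.append(self.delong_frame().to_string(index=False))
        lines.append("")
        lines.append("## Selected trees")
        for model, tree in sorted(self.trees.items()):
            lines.append(f"### {model}")
            lines.append(render_tree(tree))
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_frame().to_csv(out / "metrics.csv", index=False)
        self.auc_frame().to_csv(out / "auc.csv", index=False)
        self.delong_frame().to_csv(out / "delong.csv", index=False)
        self.sweep_table.to_csv(out / "sweep.csv", index=False)
        with open(out / "trees.json", "w") as fh:
            json.dump(self.trees, fh, indent=2)
        (out / "summary.txt").write_text(self.summary_text())


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    if config.data_path is not None:
        df = read_cohort(config.data_path)
    else:
        df = generate_cohort(config.cohort_spec, seed=config.seed)
    train, test = stratified_split(df, config.train_fraction,
                                   seed=config.seed + 1)
    X_train, y_train = cohort_arrays(train)
    X_test, y_test = cohort_arrays(test)
    Z_train, std = standardize(train)

    search = SearchConfig(restarts=config.search.restarts,
                          iterations=config.search.iterations,
                          move_probs=config.search.move_probs,
                          min_node_size=config.search.min_node_size,
                          seed=config.seed + 2)
    sweep = hyperparameter_sweep(Z_train, y_train, std, config.prior_sd,
                                 search, config.alphas, config.betas,
                                 config.threshold)
    bltree = sweep.tree

    gini_tree = cart_mod.select_subtree_cv(
        X_train, y_train, "gini", config.cart_folds, config.seed + 3,
        config.cart_min_split, config.cart_min_leaf)
    entropy_tree = cart_mod.select_subtree_cv(
        X_train, y_train, "entropy", config.cart_folds, config.seed + 4,
        config.cart_min_split, config.cart_min_leaf)

    datasets = {"train": (X_train, y_train), "test": (X_test, y_test)}
    confusions, metrics, rocs, scores = {}, {}, {}, {}
    for ds, (X, y) in datasets.items():
        labels, probs = classify(bltree, std, X, config.threshold)
        per_model = {
            "bltreed": (labels, probs),
            "cart_gini": (cart_mod.predict_cart(gini_tree, X),
                          cart_mod.leaf_scores(gini_tree, X)),
            "cart_entropy": (cart_mod.predict_cart(entropy_tree, X),
                             cart_mod.leaf_scores(entropy_tree, X)),
        }
        for model, (lab, sc) in per_model.items():
            key = (model, ds)
            confusions[key] = confusion(lab, y)
            metrics[key] = compute_metrics(confusions[key])
            rocs[key] = roc_auc(sc, y)
            scores[key] = sc

    delong = {}
    for i, a in enumerate(MODEL_NAMES):
        for b in MODEL_NAMES[i + 1:]:
            delong[(a, b)] = delong_test(scores[(a, "test")],
                                         scores[(b, "test")], y_test)

    trees = {
        "bltreed": tree_to_dict(bltree, standardization=std),
        "cart_gini": _cart_to_dict(gini_tree),
        "cart_entropy": _cart_to_dict(entropy_tree),
    }
    report = AnalysisReport(
        config=config.provenance(),
        selected_prior=(sweep.params.alpha, sweep.params.beta),
        confusions=confusions, metrics=metrics, rocs=rocs, delong=delong,
        trees=trees, sweep_table=sweep.table)
    if not report.audit():
        raise RuntimeError("internal consistency audit failed")
    return report


def _cart_to_dict(tree: cart_mod.CartTree) -> dict:
    def rec(node, node_id):
        nid = node_id[0]
        node_id[0] += 1
        d = {"id": nid, "depth": node.depth,
             "counts": [int(node.counts[0]), int(node.counts[1])]}
        if node.is_leaf:
            d["leaf"] = True
            d["majority"] = int(node.majority)
        else:
            d["leaf"] = False
            d["rule"] = {"var": PREDICTORS[node.var],
                         "threshold": float(node.threshold)}
            d["left"] = rec(node.left, node_id)
            d["right"] = rec(node.right, node_id)
        return d

    return {"tree": rec(tree.root, [0]), "n_train": tree.n_train}


# ---------------------------------------------------------------------------
# Text rendering of serialized trees
# ---------------------------------------------------------------------------

def render_tree(serialized: dict) -> str:
    """Indented text diagram of a serialized tree.

    Internal nodes show their split rule; terminal nodes show either the
    logistic coefficients (treed model) or class counts/majority (CART).
    """
    if "tree" not in serialized:
        raise ValueError("malformed serialization: missing 'tree'")
    lines: list[str] = []

    def rec(nd: dict) -> None:
        pad = "  " * nd["depth"]
        if nd.get("leaf"):
            extra = ""
            if "coefficients" in nd:
                coefs = ", ".join(f"{c:.3f}" for c in nd["coefficients"])
                extra = f" coef=[{coefs}]"
            if "majority" in nd:
                cls = "bTT" if nd["majority"] == 1 else "IDA"
                extra = (f" counts={nd['counts']} -> {cls}")
            lines.append(f"{pad}[d{nd['depth']}] leaf{extra}")
        else:
            rule = nd["rule"]
            # repr keeps full precision so parsing round-trips exactly
            lines.append(f"{pad}[d{nd['depth']}] "
                         f"{rule['var']} <= {float(rule['threshold'])!r}")
            rec(nd["left"])
            rec(nd["right"])

    rec(serialized["tree"])
    return "\n".join(lines)


def parse_rendered_tree(text: str) -> dict:
    """Structure-only inverse of :func:`render_tree` (round-trip check)."""
    entries = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        depth = int(stripped.split("]")[0][2:])
        body = stripped.split("] ", 1)[1]
        if body.startswith("leaf"):
            entries.append({"depth": depth, "leaf": True})
        else:
            var, _, thr = body.partition(" <= ")
            entries.append({"depth": depth, "leaf": False, "var": var,
                            "threshold": float(thr)})
    pos = [0]

    def build(depth: int) -> dict:
        nd = entries[pos[0]]
        if nd["depth"] != depth:
            raise ValueError("malformed rendering: depth mismatch")
        pos[0] += 1
        if nd["leaf"]:
            return {"depth": depth, "leaf": True}
        return {"depth": depth, "leaf": False,
                "rule": {"var": nd["var"], "threshold": nd["threshold"]},
                "left": build(depth + 1), "right": build(depth + 1)}

    out = {"tree": build(0)}
    if pos[0] != len(entries):
        raise ValueError("malformed rendering: trailing nodes")
    return out
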