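"""Diagnostic-accuracy evaluation: confusion matrices, the metric battery
with exact confidence intervals, ROC/AUC with DeLong variance, and the
DeLong paired AUC comparison.

The positive class throughout is bTT (label 1).  Proportion metrics carry
Clopper-Pearson exact binomial 95% intervals (beta-quantile form);
likelihood ratios carry Simel-style log-method intervals; Youden's index
carries the interval implied by summing the sensitivity and specificity
bounds.  Display rounding follows the conventions of diagnostic-accuracy
tables: percentages to integers (half away from zero), likelihood ratios to
two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "RocResult",
    "DelongResult",
    "confusion",
    "compute_metrics",
    "exact_ci",
    "likelihood_ratio_ci",
    "roc_auc",
    "delong_test",
    "round_half_away",
    "auc_band",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (numpy/python round-half-even differs)."""
    if not math.isfinite(x):
        return x
    f = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN with bTT as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must be non-empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


def confusion(predicted, truth) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true labels must have equal length")
    for arr in (predicted, truth):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((predicted == 1) & (truth == 1))),
        fp=int(np.sum((predicted == 1) & (truth == 0))),
        fn=int(np.sum((predicted == 0) & (truth == 1))),
        tn=int(np.sum((predicted == 0) & (truth == 0))),
    )


def exact_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval (beta-quantile form)."""
    if trials <= 0 or not (0 <= successes <= trials):
        raise ValueError(f"invalid counts {successes}/{trials}")
    a = (1.0 - level) / 2.0
    lo = 0.0 if successes == 0 else float(
        beta_dist.ppf(a, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        beta_dist.ppf(1.0 - a, successes + 1, trials - successes))
    return lo, hi


@dataclass(frozen=True)
class Metric:
    """Point estimate with confidence bounds; NaN marks undefined."""

    value: float
    lo: float
    hi: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.value)


@dataclass
class MetricReport:
    """The full accuracy battery for one model on one dataset."""

    counts: ConfusionCounts
    level: float
    tpr: Metric
    tnr: Metric
    fpr: Metric
    fnr: Metric
    ppv: Metric
    npv: Metric
    accuracy: Metric
    youden: Metric
    plr: Metric
    nlr: Metric

    PERCENT_METRICS = ("tpr", "tnr", "fpr", "fnr", "ppv", "npv",
                       "accuracy", "youden")
    RATIO_METRICS = ("plr", "nlr")

    def display(self) -> dict[str, str]:
        """Rounded strings: percentages to integers, ratios to 2 decimals."""
        out = {}
        for name in self.PERCENT_METRICS:
            m: Metric = getattr(self, name)
            if not m.defined:
                out[name] = "undefined"
                continue
            out[name] = (f"{round_half_away(100 * m.value):.0f}"
                         f"({round_half_away(100 * m.lo):.0f}, "
                         f"{round_half_away(100 * m.hi):.0f})")
        for name in self.RATIO_METRICS:
            m = getattr(self, name)
            if not m.defined:
                out[name] = "undefined"
                continue
            nd = 0 if name == "plr" else 2
            out[name] = (f"{round_half_away(m.value, 2):.2f}"
                         f"({round_half_away(m.lo, nd):.{nd}f}, "
                         f"{round_half_away(m.hi, nd):.{nd}f})")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.PERCENT_METRICS + self.RATIO_METRICS:
            m = getattr(self, name)
            rows.append((name, m.value, m.lo, m.hi))
        return pd.DataFrame(rows, columns=["metric", "estimate", "ci_lo", "ci_hi"])


def likelihood_ratio_ci(counts: ConfusionCounts,
                        level: float = 0.95) -> tuple[tuple[float, float],
                                                      tuple[float, float]]:
    """Log-method intervals for PLR and NLR.

    SE(ln LR) uses the standard diagnostic-likelihood-ratio variance; a
    ratio with a zero numerator or denominator count is undefined (NaN).
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    npos, nneg = counts.n_positive, counts.n_negative
    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    if npos == 0 or nneg == 0:
        return (math.nan, math.nan), (math.nan, math.nan)
    if tp > 0 and fp > 0:
        plr = (tp / npos) / (fp / nneg)
        se = math.sqrt(1 / tp - 1 / npos + 1 / fp - 1 / nneg)
        plr_ci = (plr * math.exp(-z * se), plr * math.exp(z * se))
    else:
        plr_ci = (math.nan, math.nan)
    if fn > 0 and tn > 0:
        nlr = (fn / npos) / (tn / nneg)
        se = math.sqrt(1 / fn - 1 / npos + 1 / tn - 1 / nneg)
        nlr_ci = (nlr * math.exp(-z * se), nlr * math.exp(z * se))
    else:
        nlr_ci = (math.nan, math.nan)
    return plr_ci, nlr_ci


def compute_metrics(counts: ConfusionCounts, level: float = 0.95) -> MetricReport:
    """TPR/TNR/FPR/FNR/PPV/NPV/accuracy/Youden with exact CIs; PLR/NLR with
    log-method CIs.  Zero denominators yield NaN (undefined), never raise."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    npos, nneg, n = counts.n_positive, counts.n_negative, counts.total

    def prop(s, t) -> Metric:
        if t == 0:
            return Metric(math.nan, math.nan, math.nan)
        lo, hi = exact_ci(s, t, level)
        return Metric(s / t, lo, hi)

    tpr, tnr = prop(tp, npos), prop(tn, nneg)
    fnr, fpr = prop(fn, npos), prop(fp, nneg)
    ppv, npv = prop(tp, tp + fp), prop(tn, tn + fn)
    accuracy = prop(tp + tn, n)
    if tpr.defined and tnr.defined:
        youden = Metric(tpr.value + tnr.value - 1.0,
                        tpr.lo + tnr.lo - 1.0, tpr.hi + tnr.hi - 1.0)
    else:
        youden = Metric(math.nan, math.nan, math.nan)
    plr_ci, nlr_ci = likelihood_ratio_ci(counts, level)
    plr_val = (tpr.value / fpr.value
               if tpr.defined and fpr.defined and fpr.value > 0 else math.nan)
    nlr_val = (fnr.value / tnr.value
               if fnr.defined and tnr.defined and tnr.value > 0 else math.nan)
    # perfect-classifier edges: the ratio itself is defined even when its
    # log-method CI is not
    if tpr.defined and fpr.defined and fpr.value == 0:
        plr_val = math.inf if tpr.value > 0 else math.nan
    return MetricReport(counts=counts, level=level, tpr=tpr, tnr=tnr, fpr=fpr,
                        fnr=fnr, ppv=ppv, npv=npv, accuracy=accuracy,
                        youden=youden,
                        plr=Metric(plr_val, *plr_ci),
                        nlr=Metric(nlr_val, *nlr_ci))


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

AUC_BANDS = ((0.9, "excellent differentiation"),
             (0.8, "very good differentiation"),
             (0.7, "good differentiation"),
             (0.6, "sufficient differentiation"),
             (0.5, "bad differentiation"))


def auc_band(auc: float) -> str:
    for cut, label in AUC_BANDS:
        if auc > cut:
            return label
    return "not useful for discrimination"


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float
    ci: tuple[float, float]
    band: str

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j < x.size and xs[j] == xs[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and the DeLong structural components (V10 per positive, V01 per
    negative), via the midrank formulation."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (np.sum(all_ranks[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def roc_auc(scores, labels, level: float = 0.95) -> RocResult:
    """Empirical ROC, trapezoidal AUC (= Mann-Whitney concordance with ties
    counted 1/2), DeLong SE, and Wald CI truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    # ROC points over the distinct score thresholds, descending
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    m = int(np.sum(labels)); n = labels.size - m
    tpr = np.r_[0.0, tps / m]
    fpr = np.r_[0.0, fps / n]
    auc, v10, v01 = _delong_components(scores, labels)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, se=se, ci=ci,
                     band=auc_band(auc))


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    difference: float
    z: float
    p_value: float


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """DeLong paired comparison of two AUCs on identical samples.

    Two-sided p-value from the normal approximation with the paired DeLong
    covariance.  Identical score vectors give difference 0 and p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_two_class(labels)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("paired scores must align with the labels")
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    diff = auc_a - auc_b
    if np.array_equal(scores_a, scores_b):
        return DelongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) / m if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) / n if n > 1 else np.zeros((2, 2))
    s = s10 + s01
    var = s[0, 0] + s[1, 1] - 2.0 * s[0, 1]
    if var <= 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if not math.isfinite(z) and diff == 0 else 2.0 * float(norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, diff, float(z), min(1.0, p))
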