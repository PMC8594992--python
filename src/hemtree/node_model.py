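"""Per-terminal-node Bayesian logistic regression and its Laplace marginal.

Each terminal node of a logit treed model carries a logistic regression of
the binary diagnosis on the (standardized) predictors.  The coefficient
prior is zero-mean spherical Gaussian, ``B ~ N(0, prior_sd^2 I)``; the
node's contribution to the integrated likelihood

    p(y | X, T) = prod_i  int prod_h p(y_ih | x_ih, B_i) p(B_i) dB_i

has no closed form and is evaluated with the Laplace approximation around
the posterior mode (MAP), found by damped Newton iteration.  The Gaussian
prior makes the log posterior strictly concave, so the mode is unique and
finite even under complete separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .tree_core import PREDICTORS, TreeModel

__all__ = [
    "StandardizationParams",
    "NodeLogisticModel",
    "IntegratedLikelihood",
    "NodeFitError",
    "standardize",
    "node_log_posterior",
    "fit_node_map",
    "log_marginal_node",
    "log_marginal_tree",
    "predict_node",
]


class NodeFitError(RuntimeError):
    """MAP fit or Laplace curvature failed for a node."""


@dataclass(frozen=True)
class StandardizationParams:
    """Training-set location/scale (mean, SD with denominator n-1)."""

    mean: np.ndarray
    scale: np.ndarray
    columns: tuple[str, ...] = PREDICTORS

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.mean


@dataclass
class NodeLogisticModel:
    """MAP logistic coefficients (intercept first) on the standardized scale."""

    coefficients: np.ndarray
    prior_sd: float = 20.0
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")


@dataclass
class IntegratedLikelihood:
    """Per-leaf Laplace log-marginal contributions and their sum."""

    node_values: list[float] = field(default_factory=list)
    total: float = 0.0


def standardize(train) -> tuple[np.ndarray, StandardizationParams]:
    """Center/scale each predictor to mean 0, SD 1 on the training set.

    Accepts a cohort DataFrame (uses the canonical predictor columns) or a
    raw predictor matrix.  Test data must be transformed with the returned
    params, never re-standardized on its own statistics.
    """
    if isinstance(train, pd.DataFrame):
        X = train[list(PREDICTORS)].to_numpy(dtype=float)
        cols = PREDICTORS
    else:
        X = np.asarray(train, dtype=float)
        cols = tuple(f"x{i}" for i in range(X.shape[1]))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    bad = np.where(scale <= 0)[0]
    if bad.size:
        names = [cols[i] for i in bad]
        raise ValueError(f"zero-variance predictor(s): {names}; "
                         "standardization undefined")
    params = StandardizationParams(mean=mean, scale=scale, columns=cols)
    return params.transform(X), params


def _design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def node_log_posterior(coefficients: np.ndarray, X: np.ndarray,
                       y: np.ndarray, prior_sd: float) -> float:
    """Bernoulli log-likelihood (logistic link) + Gaussian log prior."""
    b = np.asarray(coefficients, dtype=float)
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    X1 = _design(X)
    if X1.shape[1] != b.size:
        raise ValueError(f"dimension mismatch: {X1.shape[1]} columns "
                         f"(incl. intercept) vs {b.size} coefficients")
    eta = X1 @ b
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = b.size
    logprior = float(-0.5 * p * np.log(2.0 * np.pi * prior_sd**2)
                     - 0.5 * np.dot(b, b) / prior_sd**2)
    return loglik + logprior


def _posterior_parts(b, X1, y, prior_sd):
    eta = X1 @ b
    mu = expit(eta)
    lp = (np.sum(y * eta - np.logaddexp(0.0, eta))
          - 0.5 * b.size * np.log(2.0 * np.pi * prior_sd**2)
          - 0.5 * np.dot(b, b) / prior_sd**2)
    grad = X1.T @ (y - mu) - b / prior_sd**2
    return float(lp), grad, mu


def fit_node_map(X: np.ndarray, y: np.ndarray, prior_sd: float = 20.0,
                 tol: float = 1e-8, max_iter: int = 100,
                 start: np.ndarray | None = None) -> NodeLogisticModel:
    """Damped-Newton maximizer of the node log posterior.

    Converged when the gradient max-norm drops below ``tol``; steps are
    halved (up to 30 times) whenever the posterior does not increase.
    """
    X1 = _design(X)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    p = X1.shape[1]
    b = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    lp, grad, mu = _posterior_parts(b, X1, y, prior_sd)
    n_iter = 0
    converged = np.max(np.abs(grad)) < tol
    while not converged and n_iter < max_iter:
        n_iter += 1
        w = mu * (1.0 - mu)
        H = X1.T @ (X1 * w[:, None]) + np.eye(p) / prior_sd**2
        try:
            step = cho_solve(cho_factor(H), grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NodeFitError("non-positive-definite Newton system") from exc
        scale = 1.0
        noise = 1e-9 * (1.0 + abs(lp))  # concavity: only float noise can dip
        for _ in range(30):
            lp_new, grad_new, mu_new = _posterior_parts(b + scale * step, X1, y, prior_sd)
            if lp_new >= lp - noise:
                break
            scale *= 0.5
        b = b + scale * step
        lp, grad, mu = lp_new, grad_new, mu_new
        converged = np.max(np.abs(grad)) < tol
    return NodeLogisticModel(coefficients=b, prior_sd=prior_sd,
                             converged=bool(converged), n_iter=n_iter)


def _neg_hessian(b, X1, prior_sd):
    mu = expit(X1 @ b)
    w = mu * (1.0 - mu)
    return X1.T @ (X1 * w[:, None]) + np.eye(b.size) / prior_sd**2


def log_marginal_node(X: np.ndarray, y: np.ndarray,
                      prior_sd: float = 20.0) -> float:
    """Laplace log marginal likelihood of one node's data block.

    log p(y|X) ~= log posterior at MAP + (p/2) log(2 pi)
                  - (1/2) log det(negative Hessian at MAP).
    """
    model = fit_node_map(X, y, prior_sd)
    if not model.converged:
        raise NodeFitError("MAP fit did not converge")
    X1 = _design(X)
    b = model.coefficients
    lp = node_log_posterior(b, X, y, prior_sd)
    H = _neg_hessian(b, X1, prior_sd)
    try:
        c, _ = cho_factor(H)
    except np.linalg.LinAlgError as exc:
        raise NodeFitError("negative Hessian not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return lp + 0.5 * b.size * np.log(2.0 * np.pi) - 0.5 * logdet


def log_marginal_tree(tree: TreeModel, X: np.ndarray, y: np.ndarray,
                      prior_sd: float = 20.0,
                      min_node_size: int = 1) -> IntegratedLikelihood:
    """Sum of Laplace node marginals over the tree's terminal data blocks."""
    y = np.asarray(y)
    out = IntegratedLikelihood()
    for idx in tree.leaf_blocks(X):
        if idx.size < min_node_size:
            raise NodeFitError(
                f"terminal node with {idx.size} < {min_node_size} samples")
        v = log_marginal_node(X[idx], y[idx], prior_sd)
        out.node_values.append(v)
    out.total = float(np.sum(out.node_values))
    return out


def predict_node(model: NodeLogisticModel, X: np.ndarray) -> np.ndarray:
    """P(class = bTT) via inverse logit of the node's linear predictor."""
    X1 = _design(X)
    return expit(X1 @ model.coefficients)
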