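import numpy as np
import pytest

from _oracles import quadrature_log_marginal
from hemtree.node_model import (NodeFitError, NodeLogisticModel,
                                fit_node_map, log_marginal_node,
                                log_marginal_tree, node_log_posterior,
                                predict_node, standardize)
from hemtree.tree_core import Node, SplitRule, TreeModel


class TestStandardize:
    def test_train_moments(self, default_cohort):
        Z, params = standardize(default_cohort)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_inverse_roundtrip(self, default_cohort):
        Z, params = standardize(default_cohort)
        X = default_cohort[["mcv", "mch", "hb", "rdw"]].to_numpy()
        assert np.allclose(params.inverse_transform(Z), X, atol=1e-10)

    def test_test_data_uses_train_params(self):
        rng = np.random.default_rng(0)
        train = rng.normal(10.0, 2.0, (200, 4))
        test = rng.normal(20.0, 5.0, (50, 4))  # deliberately shifted
        _, params = standardize(train)
        Z_test = params.transform(test)
        # transformed with *train* location: test means stay far from 0
        assert np.all(np.abs(Z_test.mean(axis=0)) > 2.0)

    def test_zero_variance_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(X)


class TestNodeLogPosterior:
    def test_zero_coefficients_parts(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        y = np.array([0, 1] * 4)
        sd = 20.0
        p = 3
        lp = node_log_posterior(np.zeros(p), X, y, sd)
        prior_at_zero = -0.5 * p * np.log(2 * np.pi * sd**2)
        assert lp == pytest.approx(8 * np.log(0.5) + prior_at_zero, abs=1e-12)

    def test_rejects_nonbinary_outcomes(self):
        with pytest.raises(ValueError):
            node_log_posterior(np.zeros(2), np.ones((3, 1)),
                               np.array([0, 1, 2]), 20.0)

    def test_gradient_zero_at_map(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2))
        y = (rng.random(60) < 0.4).astype(int)
        model = fit_node_map(X, y, prior_sd=20.0)
        b = model.coefficients
        eps = 1e-6
        for j in range(b.size):
            e = np.zeros_like(b)
            e[j] = eps
            num_grad = (node_log_posterior(b + e, X, y, 20.0)
                        - node_log_posterior(b - e, X, y, 20.0)) / (2 * eps)
            assert abs(num_grad) < 1e-4


class TestFitNodeMap:
    def test_finite_under_complete_separation(self):
        X = np.linspace(-1, 1, 30).reshape(-1, 1)
        y = np.ones(30, dtype=int)
        model = fit_node_map(X, y, prior_sd=20.0)
        assert model.converged
        assert np.all(np.isfinite(model.coefficients))
        assert np.all(np.abs(model.coefficients) < 200)

    def test_null_data_gives_null_coefficients(self):
        rng = np.random.default_rng(3)
        n = 5000
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < 0.5).astype(int)  # independent of X
        model = fit_node_map(X, y, prior_sd=20.0)
        assert np.all(np.abs(model.coefficients) < 0.1)

    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.normal(size=(n, 1))
        truth = np.array([0.5, 2.0])
        p = 1.0 / (1.0 + np.exp(-(truth[0] + truth[1] * x[:, 0])))
        y = (rng.random(n) < p).astype(int)
        model = fit_node_map(x, y, prior_sd=20.0)
        X1 = np.hstack([np.ones((n, 1)), x])
        mu = 1.0 / (1.0 + np.exp(-(X1 @ model.coefficients)))
        H = X1.T @ (X1 * (mu * (1 - mu))[:, None]) + np.eye(2) / 20.0**2
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        assert np.all(np.abs(model.coefficients - truth) < 3 * se)

    def test_two_starts_reach_same_optimum(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 0.3).astype(int)
        a = fit_node_map(X, y, 20.0)
        b = fit_node_map(X, y, 20.0, start=rng.normal(scale=3.0, size=3))
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-6)


class TestLogMarginalNode:
    def test_tiny_prior_collapses_to_null_model(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 1))
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        lm = log_marginal_node(X, y, prior_sd=1e-4)
        assert lm == pytest.approx(10 * np.log(0.5), abs=0.01)

    def test_intercept_only_matches_quadrature(self):
        rng = np.random.default_rng(7)
        y = (rng.random(20) < 0.7).astype(int)
        X = np.empty((20, 0))
        lap = log_marginal_node(X, y, prior_sd=20.0)
        quad = quadrature_log_marginal(np.empty((20, 0)), y, 20.0)
        assert abs(lap - quad) < 0.05

    def test_one_predictor_matches_quadrature(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 1))
        p = 1.0 / (1.0 + np.exp(-(0.5 + 1.5 * x[:, 0])))
        y = (rng.random(30) < p).astype(int)
        lap = log_marginal_node(x, y, prior_sd=20.0)
        quad = quadrature_log_marginal(x, y, 20.0)
        assert abs(lap - quad) < 0.1

    def test_laplace_accuracy_over_random_nodes(self):
        # seeded property sweep over 1-2 dimensional nodes
        rng = np.random.default_rng(9)
        for _ in range(15):
            n = int(rng.integers(20, 60))
            dim = int(rng.integers(0, 2))      # 0 or 1 slope columns
            sd = float(rng.uniform(2.0, 25.0))
            x = rng.normal(size=(n, dim))
            eta = rng.normal(scale=1.0) + (x @ rng.normal(size=dim)
                                           if dim else 0.0)
            y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
            lap = log_marginal_node(x, y, prior_sd=sd)
            quad = quadrature_log_marginal(x, y, sd)
            assert abs(lap - quad) < 0.1


class TestLogMarginalTree:
    def test_root_only_equals_single_node(self, toy_1d):
        X, y = toy_1d
        tree = TreeModel(Node(0))
        il = log_marginal_tree(tree, X, y, 20.0, min_node_size=4)
        assert il.total == pytest.approx(log_marginal_node(X, y, 20.0))
        assert len(il.node_values) == 1

    def test_small_leaf_rejected(self, toy_1d):
        X, y = toy_1d
        ts = np.sort(X[:, 0])
        tree = TreeModel(Node(0, SplitRule(0, float((ts[0] + ts[1]) / 2)),
                              Node(1), Node(1)))
        with pytest.raises(NodeFitError):
            log_marginal_tree(tree, X, y, 20.0, min_node_size=4)

    def test_deterministic(self, toy_1d):
        X, y = toy_1d
        tree = TreeModel(Node(0))
        a = log_marginal_tree(tree, X, y, 20.0, 4).total
        b = log_marginal_tree(tree, X, y, 20.0, 4).total
        assert a == b

    def test_null_split_changes_only_laplace_constants(self):
        # exchangeable outcomes: splitting cannot improve fit quality, so
        # the total moves only by O(1) Laplace constant terms
        rng = np.random.default_rng(10)
        n = 400
        X = rng.normal(size=(n, 1))
        y = (rng.random(n) < 0.5).astype(int)
        root_only = TreeModel(Node(0))
        split = TreeModel(Node(0, SplitRule(0, float(np.median(X))),
                               Node(1), Node(1)))
        a = log_marginal_tree(root_only, X, y, 20.0, 10).total
        b = log_marginal_tree(split, X, y, 20.0, 10).total
        assert abs(a - b) < 10.0


class TestPredictNode:
    def test_zero_coefficients_give_half(self):
        m = NodeLogisticModel(coefficients=np.zeros(5))
        assert predict_node(m, np.ones((1, 4)))[0] == pytest.approx(0.5)

    def test_hand_computed_inverse_logit(self):
        m = NodeLogisticModel(coefficients=np.array([1.0, -2.0]))
        assert predict_node(m, np.array([[0.5]]))[0] == pytest.approx(0.5)

    def test_monotone_in_positive_slope(self):
        m = NodeLogisticModel(coefficients=np.array([0.0, 1.5]))
        p = predict_node(m, np.array([[0.0], [1.0], [2.0]]))
        assert np.all(np.diff(p) > 0)

    def test_rescaling_invariance_end_to_end(self):
        rng = np.random.default_rng(11)
        n = 300
        X = rng.uniform(5, 15, (n, 4))
        y = (rng.random(n) < 0.4).astype(int)
        X_test = rng.uniform(5, 15, (20, 4))
        scale = np.array([10.0, 0.1, 3.0, 7.0])
        shift = np.array([1.0, -2.0, 0.0, 5.0])

        def pipeline(train, test):
            Z, params = standardize(train)
            model = fit_node_map(Z, y, 20.0)
            return predict_node(model, params.transform(test))

        p1 = pipeline(X, X_test)
        p2 = pipeline(X * scale + shift, X_test * scale + shift)
        assert np.allclose(p1, p2, atol=1e-8)
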