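"""Nodewise LASSO estimation: oracle equivalence, edge rules, invariants."""
import warnings

import numpy as np
import pytest

import netoutcome as no
from netoutcome.estimate import (
    EstimationConfig,
    NetworkModel,
    NodewiseFit,
    _fit_l1_logistic,
    combine_edges,
    compute_predictability,
    design_matrix,
    fit_nodewise,
)

CFG = EstimationConfig(cv_seed=13)


def _manual_fit(coefs):
    """NodewiseFit stubs carrying only standardized coefficients."""
    m = len(coefs)
    return [
        NodewiseFit(i, "gaussian", np.asarray(c, dtype=float), np.asarray(c, dtype=float),
                    0.0, 0.1, ())
        for i, c in enumerate(coefs)
    ]


class TestCombineEdges:
    def test_and_rule_averages_shared_sign(self):
        fits = _manual_fit([[0.0, 0.30], [0.20, 0.0]])
        adj, undef = combine_edges(fits, "AND")
        assert adj[0, 1] == pytest.approx(0.25)
        assert not undef[0, 1]

    def test_and_rule_drops_one_sided_terms_but_or_keeps_them(self):
        fits = _manual_fit([[0.0, 0.30], [0.0, 0.0]])
        adj_and, _ = combine_edges(fits, "AND")
        adj_or, _ = combine_edges(fits, "OR")
        assert adj_and[0, 1] == 0.0
        assert adj_or[0, 1] == pytest.approx(0.15)

    def test_conflicting_signs_flagged_sign_undefined(self):
        fits = _manual_fit([[0.0, 0.30], [-0.20, 0.0]])
        adj, undef = combine_edges(fits, "AND")
        assert adj[0, 1] == pytest.approx(0.25)
        assert undef[0, 1]

    def test_adjacency_symmetric_zero_diagonal(self, default_network):
        adj = default_network.adjacency
        np.testing.assert_array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)


class TestNodewiseFit:
    @pytest.mark.parametrize("node", [0, 17])
    def test_lambda_max_zeroes_every_coefficient(self, small_cohort, node):
        fit = fit_nodewise(small_cohort, node, CFG)
        lmax = fit.cv_error_curve[0][0]
        at_max = fit_nodewise(small_cohort, node, CFG, fixed_lambda=lmax)
        assert np.all(at_max.coef_std == 0.0)

    def test_unpenalized_gaussian_matches_ols(self, small_cohort):
        import statsmodels.api as sm

        Z, _, _ = design_matrix(small_cohort)
        node = no.RETARDATION
        fit = fit_nodewise(small_cohort, node, CFG, fixed_lambda=0.0)
        X = np.delete(Z, node, axis=1)
        ref = sm.OLS(Z[:, node], sm.add_constant(X)).fit()
        got = np.delete(fit.coef_raw, node)
        np.testing.assert_allclose(got, ref.params[1:], atol=1e-4)
        assert fit.intercept_raw == pytest.approx(ref.params[0], abs=1e-4)

    def test_unpenalized_logistic_matches_ml(self, small_cohort):
        import statsmodels.api as sm

        Z, _, _ = design_matrix(small_cohort)
        fit = fit_nodewise(small_cohort, 17, CFG, fixed_lambda=0.0)
        ref = sm.Logit(Z[:, 17], sm.add_constant(Z[:, :17])).fit(disp=0)
        np.testing.assert_allclose(fit.coef_raw[:17], ref.params[1:], atol=1e-3)

    def test_penalized_logistic_matches_saga(self, small_cohort):
        """Dual route: the coordinate-descent path against sklearn's saga."""
        from sklearn.linear_model import LogisticRegression

        Z, _, _ = design_matrix(small_cohort)
        y = Z[:, 17].astype(int)
        X = (Z[:, :17] - Z[:, :17].mean(0)) / Z[:, :17].std(0)
        lam = 0.02
        coef, b0 = _fit_l1_logistic(X, y, lam)
        ref = LogisticRegression(
            penalty="l1", solver="saga", C=1.0 / (len(y) * lam), tol=1e-10, max_iter=50000
        ).fit(X, y)
        np.testing.assert_allclose(coef, ref.coef_.ravel(), atol=1e-6)
        assert b0 == pytest.approx(float(ref.intercept_[0]), abs=1e-6)

    def test_retained_count_monotone_along_lambda_grid(self, small_cohort):
        fit = fit_nodewise(small_cohort, 0, CFG)
        lambdas = [lam for lam, _ in fit.cv_error_curve][::6]
        counts = [
            len(fit_nodewise(small_cohort, 0, CFG, fixed_lambda=lam).retained())
            for lam in lambdas  # descending lambda
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_cv_is_deterministic_given_seed(self, small_cohort):
        f1 = fit_nodewise(small_cohort, 5, CFG)
        f2 = fit_nodewise(small_cohort, 5, CFG)
        assert f1.selected_lambda == f2.selected_lambda
        np.testing.assert_array_equal(f1.coef_std, f2.coef_std)

    def test_constant_predictor_excluded_with_warning(self, scale, small_cohort):
        scores = small_cohort.scores.copy()
        scores[:, 16] = 1.0
        coh = no.CohortTable(scores, small_cohort.outcome, scale)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_nodewise(coh, 0, CFG)
        assert fit.coef_std[16] == 0.0 and 16 in fit.dropped

    def test_single_class_outcome_is_estimation_error(self, scale, small_cohort):
        coh = no.CohortTable(small_cohort.scores, np.ones(small_cohort.n_patients), scale)
        with pytest.raises(no.EstimationError, match="single class"):
            fit_nodewise(coh, 17, CFG)


class TestEstimateNetwork:
    def test_requires_minimum_sample_and_both_classes(self, scale, small_cohort):
        tiny = small_cohort.subset(np.arange(20))
        with pytest.raises(no.EstimationError):
            no.estimate_network(tiny, CFG)
        allrem = no.CohortTable(small_cohort.scores, np.ones(small_cohort.n_patients), scale)
        with pytest.raises(no.EstimationError):
            no.estimate_network(allrem, CFG)

    def test_smallest_retained_weight_positive_when_edges_exist(self, default_network):
        assert default_network.smallest_retained_weight is not None
        assert default_network.smallest_retained_weight > 0
        mags = np.abs(default_network.adjacency)
        assert default_network.smallest_retained_weight == pytest.approx(
            mags[mags > 0].min()
        )

    def test_permutation_equivariance(self, scale, small_cohort):
        """Permuting item columns permutes the adjacency identically."""
        rng = np.random.default_rng(1)
        perm = rng.permutation(17)
        pscale = no.SymptomScale(tuple(scale.items[j] for j in perm))
        pcoh = no.CohortTable(
            small_cohort.scores[:, perm], small_cohort.outcome, pscale
        )
        net = no.estimate_network(small_cohort, CFG)
        pnet = no.estimate_network(pcoh, CFG)
        full_perm = np.concatenate([perm, [17]])
        np.testing.assert_allclose(
            pnet.adjacency, net.adjacency[np.ix_(full_perm, full_perm)], atol=1e-6
        )


class TestPredictability:
    def test_empty_network_gives_zero_predictability(self, small_cohort):
        fits = [
            fit_nodewise(small_cohort, node, CFG, fixed_lambda=10.0) for node in range(18)
        ]
        Z, labels, types = design_matrix(small_cohort)
        model = NetworkModel(labels, types, np.zeros((18, 18)),
                             np.zeros((18, 18), bool), fits, np.zeros(18), None)
        pred = compute_predictability(model, small_cohort)
        np.testing.assert_allclose(pred, 0.0, atol=1e-12)

    def test_near_deterministic_node_has_high_predictability(self):
        """A node that is (almost) a function of its neighbor is almost
        fully explained by the rest of the network."""
        tri = no.SymptomScale(
            tuple(no.ItemDescriptor(lbl, 0, 4) for lbl in ("a", "b", "c"))
        )
        rng = np.random.default_rng(3)
        n = 500
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x0 = x1 + 0.01 * rng.normal(size=n)
        coh = no.CohortTable(
            np.column_stack([x0, x1, x2]), rng.binomial(1, 0.5, n), tri, discrete=False
        )
        net = no.estimate_network(coh, CFG)
        assert net.predictability[0] > 0.95

    def test_predictability_bounded(self, default_network):
        assert np.all(default_network.predictability >= 0.0)
        assert np.all(default_network.predictability <= 1.0)
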