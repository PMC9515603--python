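"""Phylogenetic covariance, GLS fits, Pagel's lambda, ANCOVA, correlations."""

import numpy as np
import pytest
from scipy import stats

from antmimic import phylo_gls as P
from antmimic import synthetic_data as S


class TestTreeToVcv:
    def test_star_tree(self):
        C = P.tree_to_vcv("(A:1,B:1,C:1);")
        M = C.reorder(["A", "B", "C"]).matrix
        assert np.allclose(M, np.eye(3))

    def test_hand_computed_three_tips(self):
        C = P.tree_to_vcv("((A:1,B:1):1,C:2);").reorder(["A", "B", "C"])
        assert np.allclose(C.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_diagonal_equals_root_to_tip_paths(self, tree70):
        C = P.tree_to_vcv(tree70)
        # independent path-walk oracle via dendropy's own distance accounting
        depths = {leaf.taxon.label: leaf.distance_from_root() for leaf in tree70.leaf_node_iter()}
        for i, lab in enumerate(C.tip_labels):
            assert C.matrix[i, i] == pytest.approx(depths[lab])

    def test_symmetric_psd(self, vcv70):
        M = vcv70.matrix
        assert np.allclose(M, M.T)
        assert np.linalg.eigvalsh(M)[0] > -1e-10

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            P.tree_to_vcv("((A:1,B),C:2);")


class TestApplyLambda:
    C3 = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_identity_at_one(self):
        assert np.allclose(P.apply_lambda(self.C3, 1.0), self.C3)

    def test_diagonal_at_zero(self):
        assert np.allclose(P.apply_lambda(self.C3, 0.0), np.diag([2.0, 2, 2]))

    def test_half(self):
        assert np.allclose(
            P.apply_lambda(self.C3, 0.5), [[2, 0.5, 0], [0.5, 2, 0], [0, 0, 2]]
        )

    def test_linearity_in_offdiagonal(self, vcv70):
        M = vcv70.matrix
        V1, V2 = P.apply_lambda(M, 0.3), P.apply_lambda(M, 0.6)
        off = ~np.eye(len(M), dtype=bool)
        assert np.allclose(V2[off], 2 * V1[off])

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            P.apply_lambda(self.C3, -3.0)


class TestMartins:
    def test_large_alpha_identity(self):
        C = P.martins_correlation("((A:1,B:1):1,C:2);", 80.0)
        assert np.allclose(C.matrix, np.eye(3), atol=1e-12)

    def test_zero_alpha_all_ones(self):
        C = P.martins_correlation("((A:1,B:1):1,C:2);", 0.0)
        assert np.allclose(C.matrix, 1.0)

    def test_closed_form_entry(self):
        # A and B are patristic distance 2 apart
        C = P.martins_correlation("((A:1,B:1):1,C:2);", 1.0).reorder(["A", "B", "C"])
        assert C.matrix[0, 1] == pytest.approx(np.exp(-2))


class TestGlsFit:
    def test_identity_covariance_equals_ols(self, rng):
        for _ in range(20):
            n = 25
            X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
            y = rng.standard_normal(n)
            f = P.gls_fit(X, y, np.eye(n))
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            assert np.abs(f.coef - ols).max() < 1e-10

    def test_scaled_identity_same_coefficients(self, rng):
        n = 15
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        f1 = P.gls_fit(X, y, np.eye(n))
        f2 = P.gls_fit(X, y, 7.3 * np.eye(n))
        assert np.abs(f1.coef - f2.coef).max() < 1e-10

    def test_exchangeable_symmetry(self):
        V = np.array([[1.0, 0.4], [0.4, 1.0]])
        f = P.gls_fit(np.ones((2, 1)), np.array([0.0, 2.0]), V)
        assert f.coef[0] == pytest.approx(1.0)

    def test_loglik_equals_mvn_density(self, vcv70, rng):
        for _ in range(20):
            n = rng.integers(4, 9)
            idx = rng.choice(70, size=n, replace=False)
            V = vcv70.matrix[np.ix_(idx, idx)]
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = rng.standard_normal(n)
            f = P.gls_fit(X, y, V)
            oracle = stats.multivariate_normal(mean=X @ f.coef, cov=f.sigma2 * V).logpdf(y)
            assert f.loglik == pytest.approx(oracle, abs=1e-8)

    def test_aic_definition(self, rng):
        n = 10
        X = np.ones((n, 1))
        f = P.gls_fit(X, rng.standard_normal(n), np.eye(n))
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_params)

    def test_singular_design_rejected(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            P.gls_fit(X, rng.standard_normal(n), np.eye(n))


class TestEstimateLambda:
    def test_negative_lambda_reachable(self, vcv70, rng):
        # overdispersed-at-tips data should push the estimate below zero
        est = P.lambda_signal(rng.standard_normal(70), vcv70)
        assert est.bounds[0] < 0
        assert est.bounds[0] <= est.lam <= est.bounds[1]

    def test_iid_noise_estimates_near_zero(self, vcv70, rng):
        lams = [P.lambda_signal(rng.standard_normal(70), vcv70).lam for _ in range(40)]
        assert abs(float(np.mean(lams))) < 0.1

    def test_brownian_data_estimates_near_one(self, vcv70, rng):
        lams = [
            P.lambda_signal(S.sim_traits_lambda(vcv70, 1.0, 1.0, 0.0, rng), vcv70).lam
            for _ in range(40)
        ]
        assert abs(float(np.mean(lams)) - 1.0) < 0.1

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            P.estimate_lambda(np.ones((3, 1)), np.zeros(3), np.eye(3))


class TestAncova:
    def test_single_level_reduces_to_regression(self, vcv70, rng):
        y, x, _ = S.sim_ancova_data(vcv70, {"insect": 0.5, "spider": 0.5}, rng)
        taxon = np.array(["spider"] * 70)
        f = P.pgls_ancova(y, x, taxon, vcv70)
        assert f.levels == ["spider"]
        assert f.interaction_F is None
        assert set(f.slopes) == {"spider"}

    def test_small_level_rejected(self, vcv70, rng):
        taxon = np.array(["spider"] * 68 + ["insect"] * 2)
        with pytest.raises(ValueError, match="fewer than 3"):
            P.pgls_ancova(rng.standard_normal(70), rng.standard_normal(70), taxon, vcv70)

    def test_opposite_slopes_recovered(self, vcv70, rng):
        hits = 0
        for _ in range(25):
            y, x, taxon = S.sim_ancova_data(vcv70, {"insect": 1.0, "spider": -1.0}, rng)
            f = P.pgls_ancova(y, x, taxon, vcv70)
            hits += f.slopes["insect"] > 0 and f.slopes["spider"] < 0
        assert hits >= 24

    def test_f_statistics_positive_with_residual_df(self, vcv70, rng):
        y, x, taxon = S.sim_ancova_data(vcv70, {"insect": 0.8, "spider": -0.8}, rng)
        f = P.pgls_ancova(y, x, taxon, vcv70)
        F, df1, df2, p = f.slope_F
        assert F >= 0 and df1 == 1 and df2 == 70 - 4 and 0 <= p <= 1


class TestPhyloCorrelation:
    def test_identical_variables(self, vcv70, rng):
        d = rng.standard_normal(70)
        assert P.phylo_correlation(d, d, vcv70) == pytest.approx(1.0)

    def test_negated_variables(self, vcv70, rng):
        d = rng.standard_normal(70)
        assert P.phylo_correlation(d, -d, vcv70) == pytest.approx(-1.0)

    def test_identity_structure_equals_pearson(self, rng):
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        got = P.phylo_correlation(a, b, None)
        assert got == pytest.approx(stats.pearsonr(a, b).statistic)

    def test_zero_variance_rejected(self, vcv70):
        with pytest.raises(ValueError, match="variance"):
            P.phylo_correlation(np.ones(70), np.arange(70.0), vcv70)


class TestStructureSelection:
    def _fit(self, aic_target, n_params):
        f = P.gls_fit(np.ones((6, 1)), np.arange(6.0), np.eye(6))
        f.n_params = n_params
        f.loglik = -(aic_target - 2 * n_params) / 2
        return f

    def test_smaller_aic_wins(self):
        fits = {"brownian": self._fit(10, 2), "pagel": self._fit(8, 3)}
        assert P.select_structure(fits) == "pagel"

    def test_tie_prefers_fewer_parameters(self):
        fits = {"pagel": self._fit(10, 3), "brownian": self._fit(10, 2)}
        assert P.select_structure(fits) == "brownian"

    def test_brownian_data_pagel_close(self, vcv70, rng):
        close = 0
        for _ in range(15):
            y = S.sim_traits_lambda(vcv70, 1.0, 1.0, 0.0, rng)
            X = np.ones((70, 1))
            brown = P.gls_fit(X, y, vcv70.matrix)
            est = P.estimate_lambda(X, y, vcv70, method="ml")
            close += abs(est.fit.aic - brown.aic) <= 2.0
        assert close >= 10  # most replicates


class TestBonferroni:
    def test_reported_color_size_not_significant(self):
        # six pairwise category relationships: threshold 0.05/6
        assert not P.bonferroni([0.04], 6)[0]

    def test_reported_color_shape_significant(self):
        assert P.bonferroni([0.0006], 6)[0]

    def test_single_test_plain_rule(self):
        assert P.bonferroni([0.049], 1)[0]
        assert not P.bonferroni([0.051], 1)[0]
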