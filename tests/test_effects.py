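import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.special import expit

from causalde import (
    CountMatrix,
    DesignMatrix,
    adjust_fdr,
    adjust_fdx,
    estimate_lfc,
    estimate_variance,
    run_contrasts,
)
from causalde.effects import test_effects as compute_test_statistics
from causalde.effects import (
    NuisanceInput,
    OutcomeFit,
    PotentialOutcomes,
    fit_outcome_models,
    fit_propensity,
    impute_potential_outcomes,
)


def _po(y1, y0):
    y1 = np.atleast_2d(np.asarray(y1, dtype=float))
    y0 = np.atleast_2d(np.asarray(y0, dtype=float))
    return PotentialOutcomes(
        y1_hat=y1, y0_hat=y0, mu1=y1, mu0=y0, pi1=np.full(y1.shape[0], 0.5)
    )


class TestAIPWImputation:
    def _ni(self, A, Y):
        n = len(A)
        return NuisanceInput(W=np.zeros((n, 1)), A=A, Y=Y, s=np.ones(n))

    def test_formula_treated_observation(self):
        # A=1, Y=10, mu1=8, pi=0.5 -> Yhat(1) = 8 + (10-8)/0.5 = 12
        ni = self._ni(np.array([1, 0]), np.array([[10.0], [0.0]]))
        mu = OutcomeFit(
            mu1=np.full((2, 1), 8.0),
            mu0=np.full((2, 1), 3.0),
            coef=None,
            flagged=np.zeros(1, bool),
        )
        po = impute_potential_outcomes(ni, mu, np.array([0.5, 0.5]))
        assert po.y1_hat[0, 0] == pytest.approx(12.0)

    def test_untreated_gets_model_prediction(self):
        ni = self._ni(np.array([0, 1]), np.array([[7.0], [1.0]]))
        mu = OutcomeFit(
            mu1=np.full((2, 1), 8.0),
            mu0=np.full((2, 1), 3.0),
            coef=None,
            flagged=np.zeros(1, bool),
        )
        po = impute_potential_outcomes(ni, mu, np.array([0.4, 0.4]))
        assert po.y1_hat[0, 0] == pytest.approx(8.0)  # indicator kills correction

    def test_unit_propensity_returns_observed(self):
        ni = self._ni(np.array([1, 0]), np.array([[10.0], [2.0]]))
        mu = OutcomeFit(
            mu1=np.full((2, 1), 4.0),
            mu0=np.full((2, 1), 4.0),
            coef=None,
            flagged=np.zeros(1, bool),
        )
        po = impute_potential_outcomes(ni, mu, np.array([1.0, 1.0]))
        assert po.y1_hat[0, 0] == pytest.approx(10.0)

    def test_brute_force_oracle(self, rng):
        n, p = 40, 5
        A = rng.binomial(1, 0.5, n).astype(float)
        A[:2] = [0, 1]
        Y = rng.poisson(5.0, (n, p)).astype(float)
        ni = self._ni(A, Y)
        mu1 = rng.uniform(1, 8, (n, p))
        mu0 = rng.uniform(1, 8, (n, p))
        pi = rng.uniform(0.2, 0.8, n)
        mu = OutcomeFit(mu1=mu1, mu0=mu0, coef=None, flagged=np.zeros(p, bool))
        po = impute_potential_outcomes(ni, mu, pi)
        for i in range(n):
            for j in range(p):
                expect1 = mu1[i, j] + (A[i] / pi[i]) * (Y[i, j] - mu1[i, j])
                expect0 = mu0[i, j] + ((1 - A[i]) / (1 - pi[i])) * (Y[i, j] - mu0[i, j])
                assert po.y1_hat[i, j] == pytest.approx(expect1, rel=1e-12)
                assert po.y0_hat[i, j] == pytest.approx(expect0, rel=1e-12)


class TestLFC:
    def test_identical_arms_zero(self):
        y = np.abs(np.random.default_rng(0).normal(5, 1, (10, 3)))
        tau, eta = estimate_lfc(_po(y, y))
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)
        np.testing.assert_allclose(eta, 0.0, atol=1e-12)

    def test_e_scaling_gives_unit_lfc(self):
        y0 = np.abs(np.random.default_rng(1).normal(5, 1, (10, 3)))
        tau, _ = estimate_lfc(_po(np.e * y0, y0))
        np.testing.assert_allclose(tau, 1.0, rtol=1e-12)

    def test_matches_column_mean_oracle(self):
        rng = np.random.default_rng(9)
        y1 = rng.uniform(0.5, 4.0, (25, 6))
        y0 = rng.uniform(0.5, 4.0, (25, 6))
        tau, eta = estimate_lfc(_po(y1, y0))
        oracle = np.log(y1.mean(axis=0) / y0.mean(axis=0))
        np.testing.assert_allclose(tau, oracle, rtol=1e-12)
        np.testing.assert_allclose(eta.mean(axis=0), 0.0, atol=1e-10)

    def test_nonpositive_arm_mean_flagged(self):
        y1 = np.full((4, 1), -1.0)
        y0 = np.ones((4, 1))
        with pytest.warns(UserWarning):
            tau, _ = estimate_lfc(_po(y1, y0))
        assert np.isnan(tau[0])


class TestVariance:
    def test_two_point_influence(self):
        sigma = estimate_variance(np.array([[1.0], [-1.0]]))
        assert sigma[0] == pytest.approx(1.0)

    def test_degenerate_zero(self):
        sigma = estimate_variance(np.zeros((5, 2)))
        np.testing.assert_allclose(sigma, 0.0)

    def test_paper_formula_mode_verbatim(self):
        eta = np.array([[1.0], [2.0], [-1.0]])
        n = 3
        expected = np.sqrt(np.sqrt(n) / (n - 1) * np.sum(eta**2))
        sigma = estimate_variance(eta, mode="paper_formula")
        assert sigma[0] == pytest.approx(expected, rel=1e-12)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            estimate_variance(np.ones((1, 1)))


class TestTests:
    def test_null_point_p_one(self):
        T, p = compute_test_statistics(np.array([0.0]), np.array([1.0]))
        assert p[0] == pytest.approx(1.0)

    def test_normal_quantile(self):
        _, p = compute_test_statistics(np.array([1.959964]), np.array([1.0]))
        assert p[0] == pytest.approx(0.05, abs=1e-6)

    def test_symmetry(self):
        _, p_pos = compute_test_statistics(np.array([1.3]), np.array([1.0]))
        _, p_neg = compute_test_statistics(np.array([-1.3]), np.array([1.0]))
        assert p_pos[0] == pytest.approx(p_neg[0], rel=1e-14)

    def test_zero_sigma_cases(self):
        T, p = compute_test_statistics(np.array([0.0, 0.5]), np.array([0.0, 0.0]))
        assert p[0] == 1.0 and p[1] == 0.0


def _bh_brute(p, alpha):
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, bool)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= alpha * i / m:
            k = i
    reject[order[:k]] = True
    return reject


def _lr_brute(p, gamma, alpha):
    m = len(p)
    order = np.argsort(p)
    sp = p[order]
    k = 0
    for i in range(1, m + 1):
        thr = (np.floor(gamma * i) + 1) * alpha / (m + np.floor(gamma * i) + 1 - i)
        if sp[i - 1] <= thr:
            k = i
        else:
            break
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestMultipleTesting:
    def test_bh_forced_arithmetic(self):
        q, _ = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, 0.04)

    def test_bh_all_ones(self):
        q, reject = adjust_fdr(np.ones(10))
        np.testing.assert_allclose(q, 1.0)
        assert not reject.any()

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=25)
        p[:5] = rng.uniform(0, 0.01, 5)
        _, reject = adjust_fdr(p, alpha=0.1)
        np.testing.assert_array_equal(reject, _bh_brute(p, 0.1))

    def test_fdx_tiny_p_rejects_all(self):
        assert adjust_fdx(np.full(8, 1e-12)).all()

    def test_fdx_p_one_rejects_none(self):
        assert not adjust_fdx(np.ones(8)).any()

    def test_fdx_matches_brute_force(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=20) ** 2
        got = adjust_fdx(p, gamma=0.1, alpha=0.05)
        np.testing.assert_array_equal(got, _lr_brute(p, 0.1, 0.05))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(1e-12, 1.0), min_size=2, max_size=40))
    def test_fdx_subset_of_fdr(self, pvals):
        p = np.asarray(pvals)
        _, rej_fdr = adjust_fdr(p, alpha=0.1)
        rej_fdx = adjust_fdx(p, gamma=0.1, alpha=0.1)
        assert not (rej_fdx & ~rej_fdr).any()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_q_monotone_in_p_order(self, pvals):
        p = np.asarray(pvals)
        q, _ = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestNuisanceModels:
    def test_constant_gene_intercept_only(self):
        n = 60
        A = np.array([0, 1] * (n // 2), dtype=float)
        Y = np.full((n, 1), 7.0)
        ni = NuisanceInput(W=np.zeros((n, 0)), A=A, Y=Y, s=np.ones(n))
        mu = fit_outcome_models(ni, dispersions=np.array([2.0]))
        np.testing.assert_allclose(mu.mu1, 7.0, rtol=1e-4)
        np.testing.assert_allclose(mu.mu0, 7.0, rtol=1e-4)

    def test_size_factor_offset_equivariance(self, rng):
        n = 200
        A = rng.binomial(1, 0.5, n).astype(float)
        A[:2] = [0, 1]
        s = rng.uniform(0.5, 2.0, n)
        mu_true = np.exp(0.5 + 0.8 * A)
        Y = rng.poisson(s * mu_true)[:, None].astype(float)
        ni1 = NuisanceInput(W=np.zeros((n, 0)), A=A, Y=Y, s=s)
        ni2 = NuisanceInput(W=np.zeros((n, 0)), A=A, Y=Y, s=2 * s)
        m1 = fit_outcome_models(ni1, dispersions=np.array([50.0]))
        m2 = fit_outcome_models(ni2, dispersions=np.array([50.0]))
        # doubling s halves the adjusted-scale predictions
        np.testing.assert_allclose(m1.mu1, 2 * m2.mu1, rtol=1e-6)

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(3)
        n = 2000
        W = rng.standard_normal((n, 2))
        A = rng.binomial(1, 0.5, n).astype(float)
        phi = 4.0
        eta = 0.8 + 0.5 * W[:, 0] - 0.4 * W[:, 1] + 0.7 * A
        mu = np.exp(eta)
        Y = rng.negative_binomial(phi, phi / (phi + mu))[:, None].astype(float)
        ni = NuisanceInput(W=W, A=A, Y=Y, s=np.ones(n))
        fit = fit_outcome_models(ni, dispersions=np.array([phi]))
        # crude SE bound: |coef - truth| within 2 * 3/sqrt(n)
        truth = np.array([0.8, 0.5, -0.4, 0.7])
        assert np.all(np.abs(fit.coef[0] - truth) < 2 * 3 / np.sqrt(n))

    def test_propensity_null_matches_treated_fraction(self):
        rng = np.random.default_rng(5)
        n = 5000
        W = rng.standard_normal((n, 3))
        A = rng.binomial(1, 0.4, n).astype(float)
        ni = NuisanceInput(W=W, A=A, Y=np.ones((n, 1)), s=np.ones(n))
        pi, _ = fit_propensity(ni, "logistic")
        assert abs(pi.mean() - A.mean()) < 0.02

    def test_propensity_clipping_on_separable_data(self):
        n = 100
        W = np.r_[np.full(50, -3.0), np.full(50, 3.0)][:, None]
        A = np.r_[np.zeros(50), np.ones(50)]
        ni = NuisanceInput(W=W, A=A, Y=np.ones((n, 1)), s=np.ones(n))
        pi, _ = fit_propensity(ni, "logistic", clip=0.01)
        assert pi.min() >= 0.01 and pi.max() <= 0.99
        assert (pi <= 0.01).any() and (pi >= 0.99).any()

    def test_propensity_slope_recovery(self):
        rng = np.random.default_rng(6)
        n = 10_000
        w = rng.standard_normal(n)
        A = rng.binomial(1, expit(w)).astype(float)
        ni = NuisanceInput(W=w[:, None], A=A, Y=np.ones((n, 1)), s=np.ones(n))
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(penalty=None, max_iter=1000).fit(w[:, None], A.astype(int))
        assert 0.9 <= lr.coef_[0, 0] <= 1.1

    def test_random_forest_cross_fitting_smoke(self):
        rng = np.random.default_rng(8)
        n = 300
        W = rng.standard_normal((n, 3))
        A = rng.binomial(1, expit(W[:, 0])).astype(float)
        ni = NuisanceInput(W=W, A=A, Y=np.ones((n, 1)), s=np.ones(n))
        pi, folds = fit_propensity(ni, "random_forest", folds=3)
        assert len(np.unique(folds)) == 3
        assert pi.min() >= 0.01 and pi.max() <= 0.99


class TestContrasts:
    def _multi_sim(self, seed=21, null=True):
        rng = np.random.default_rng(seed)
        n, p = 240, 120
        U = rng.standard_normal((n, 2))
        labels = np.array(["ctrl", "t1", "t2"])[rng.integers(0, 3, n)]
        mu = np.exp(np.log(2.0) + 0.3 * U @ rng.normal(0, 1, (2, p)) * 0.3)
        phi = 5.0
        Y = rng.negative_binomial(phi, phi / (phi + mu))
        cm = CountMatrix(Y)
        design = DesignMatrix(
            treatment=labels, covariates=rng.standard_normal((n, 1)),
            control_label="ctrl",
        )
        return cm, design

    def test_null_contrasts_modest_rejections(self):
        cm, design = self._multi_sim()
        tables = run_contrasts(cm, design, "ctrl", r=2)
        assert set(tables) == {"t1", "t2"}
        for t in tables.values():
            assert t.table.reject_fdr.mean() <= 0.05

    def test_single_level_reduces_to_binary(self):
        cm, design = self._multi_sim()
        keep = design.treatment != "t2"
        cm_b = CountMatrix(cm.counts[keep])
        d_b = DesignMatrix(
            treatment=design.treatment[keep],
            covariates=design.covariates[keep],
            control_label="ctrl",
        )
        tables = run_contrasts(cm_b, d_b, "ctrl", r=2)
        assert list(tables) == ["t1"]
        assert len(tables["t1"]) == cm.n_genes

    def test_relabeling_flips_sign(self):
        cm, design = self._multi_sim()
        keep = design.treatment != "t2"
        cm_b = CountMatrix(cm.counts[keep])
        covs = design.covariates[keep]
        tr = design.treatment[keep]
        t_fwd = run_contrasts(
            cm_b, DesignMatrix(treatment=tr.copy(), covariates=covs, control_label="ctrl"),
            "ctrl", r=0, debias=False, empirical_null=False,
        )["t1"]
        t_rev = run_contrasts(
            cm_b, DesignMatrix(treatment=tr.copy(), covariates=covs, control_label="t1"),
            "t1", r=0, debias=False, empirical_null=False,
        )["ctrl"]
        np.testing.assert_allclose(
            t_fwd.table.tau_hat, -t_rev.table.tau_hat, atol=1e-6
        )
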