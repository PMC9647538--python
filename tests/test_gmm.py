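import numpy as np
import pandas as pd
import pytest

from psytraj.cohort import AnnualSeries
from psytraj.gmm import (
    GrowthMixtureSpec,
    avg_posterior_by_modal_class,
    class_conditional_loglik,
    compute_bic,
    compute_entropy,
    design_matrices,
    fit_gmm,
    robust_standard_errors,
    simulate_from_fit,
)

_LOG2PI = np.log(2 * np.pi)


class TestDesignMatrices:
    def test_linear_shape(self):
        X, Z = design_matrices(10, 1)
        assert X.shape == (10, 2)
        assert Z.shape == (10, 2)

    def test_quadratic_centred(self):
        X, _ = design_matrices(10, 2)
        assert X.shape == (10, 3)
        assert X[:, 1].sum() == pytest.approx(0.0)  # centring zeroes column 2

    def test_cubic_underdetermined(self):
        with pytest.raises(ValueError):
            design_matrices(3, 3)


class TestClassConditionalLoglik:
    def test_single_standard_normal_point(self):
        # one observed point, mean 0, unit total variance
        y = AnnualSeries("s", np.array([0.0] + [np.nan] * 9))
        X, Z = design_matrices(10, 1)
        ll = class_conditional_loglik(y, np.zeros(2), None, 1.0, X, Z)
        assert ll == pytest.approx(-0.9189385, abs=1e-6)

    def test_zero_sigma_b_reduces_to_independent(self):
        rng = np.random.default_rng(0)
        X, Z = design_matrices(6, 2)
        y = AnnualSeries("s", rng.normal(3, 1, 6).clip(0, 12), T=6)
        beta = np.array([3.0, 0.1, 0.0])
        ll_re = class_conditional_loglik(y, beta, np.zeros((2, 2)), 0.8, X, Z)
        ll_no = class_conditional_loglik(y, beta, None, 0.8, X, Z)
        assert ll_re == pytest.approx(ll_no, abs=1e-9)

    def test_matches_bruteforce_matrix_inversion(self):
        rng = np.random.default_rng(5)
        T = 5
        X, Z = design_matrices(T, 1)
        y_vals = rng.normal(5, 2, T)
        y = AnnualSeries("s", y_vals.clip(0, 12), T=T)
        beta = np.array([4.0, -0.3])
        Sb = np.array([[1.2, 0.2], [0.2, 0.4]])
        s2 = 0.7
        ll = class_conditional_loglik(y, beta, Sb, s2, X, Z)
        # independent oracle: explicit inverse and determinant
        V = Z @ Sb @ Z.T + s2 * np.eye(T)
        r = y.y - X @ beta
        oracle = -0.5 * (
            T * _LOG2PI + np.log(np.linalg.det(V)) + r @ np.linalg.inv(V) @ r
        )
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_no_observed_years_errors(self):
        y = AnnualSeries("empty", np.full(10, np.nan))
        X, Z = design_matrices(10, 1)
        with pytest.raises(ValueError, match="empty"):
            class_conditional_loglik(y, np.zeros(2), None, 1.0, X, Z)


class TestFitSingleClass:
    def test_k1_equals_ols(self):
        rng = np.random.default_rng(1)
        n, T = 80, 6
        X, _ = design_matrices(T, 2)
        Y = (X @ np.array([4.0, -0.3, 0.05]))[None, :] + rng.normal(0, 1.0, (n, T))
        fit = fit_gmm(Y, GrowthMixtureSpec(n_classes=1, degree=2, random_effects="none"))
        Xs = np.tile(X, (n, 1))
        beta_ols, *_ = np.linalg.lstsq(Xs, Y.ravel(), rcond=None)
        resid = Y.ravel() - Xs @ beta_ols
        s2 = (resid**2).mean()
        ll = -0.5 * resid.size * (np.log(2 * np.pi * s2) + 1.0)
        np.testing.assert_allclose(fit.beta[0], beta_ols, atol=1e-6)
        assert fit.sigma2 == pytest.approx(s2, abs=1e-6)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)
        assert fit.pi[0] == pytest.approx(1.0)

    def test_k1_re_equals_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n, T = 80, 5
        X, Z = design_matrices(T, 1)
        b = rng.normal(0, [1.0, 0.3], size=(n, 2))
        Y = (
            (X @ np.array([5.0, 0.5]))[None, :]
            + b[:, :1]
            + b[:, 1:] * X[:, 1][None, :]
            + rng.normal(0, 1.0, (n, T))
        )
        spec = GrowthMixtureSpec(
            n_classes=1, degree=1, random_effects="intercept_slope", tol=1e-10
        )
        fit = fit_gmm(Y, spec)
        df = pd.DataFrame(
            {
                "y": Y.ravel(),
                "t": np.tile(X[:, 1], n),
                "g": np.repeat(np.arange(n), T),
            }
        )
        md = sm.MixedLM.from_formula("y ~ t", df, re_formula="~t", groups="g").fit(
            reml=False, method="lbfgs"
        )
        assert fit.loglik == pytest.approx(md.llf, abs=1e-6)
        np.testing.assert_allclose(fit.beta[0], md.fe_params.values, atol=1e-4)

    def test_single_class_data_gives_pi_one(self):
        rng = np.random.default_rng(2)
        X, _ = design_matrices(5, 1)
        Y = (X @ np.array([3.0, 0.2]))[None, :] + rng.normal(0, 0.5, (60, 5))
        fit = fit_gmm(Y, GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none"))
        assert fit.pi.tolist() == [1.0]


@pytest.fixture(scope="module")
def two_class_fit():
    rng = np.random.default_rng(7)
    n, T = 400, 8
    X, _ = design_matrices(T, 1)
    truth_pi = 0.6
    cls = rng.random(n) < truth_pi
    mu = np.where(cls[:, None], (X @ [2.0, -0.2])[None, :], (X @ [9.0, 0.3])[None, :])
    Y = mu + rng.normal(0, 1.0, (n, T))
    spec = GrowthMixtureSpec(
        n_classes=2, degree=1, random_effects="none", n_starts=10, seed=0
    )
    return cls, Y, fit_gmm(Y, spec)


class TestFitMixture:
    def test_mixing_proportion_recovery(self, two_class_fit):
        cls, Y, fit = two_class_fit
        assert abs(fit.pi[0] - 0.6) < 0.05

    def test_beta_recovery(self, two_class_fit):
        cls, Y, fit = two_class_fit
        # 3 Monte-Carlo SEs; per-coefficient SE is ~sigma/sqrt(n_k * T)
        assert abs(fit.beta[0][0] - 2.0) < 0.25
        assert abs(fit.beta[1][0] - 9.0) < 0.3

    def test_em_monotone(self, two_class_fit):
        *_, fit = two_class_fit
        assert np.diff(fit.loglik_trace).min() > -1e-8

    def test_classes_ordered_by_share(self, two_class_fit):
        *_, fit = two_class_fit
        assert fit.pi[0] >= fit.pi[1]

    def test_posterior_rows_sum_to_one(self, two_class_fit):
        *_, fit = two_class_fit
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_label_permutation_invariance(self, two_class_fit):
        from psytraj.gmm import _build_patterns, _e_step, design_matrices as dm

        *_, fit = two_class_fit
        _, Y, _ = two_class_fit
        X, Z = dm(fit.T, fit.spec.degree)
        patterns = _build_patterns(Y, X, Z)
        perm = [1, 0]
        P2, ll2 = _e_step(
            patterns, fit.pi[perm], fit.beta[perm], fit.Sigma_b, fit.sigma2, Y.shape[0]
        )
        assert ll2 == pytest.approx(fit.loglik, abs=1e-8)
        assert compute_entropy(P2) == pytest.approx(compute_entropy(fit.posteriors), abs=1e-10)
        assert compute_bic(ll2, fit.n_params, fit.n_used) == pytest.approx(fit.bic, abs=1e-6)

    def test_mar_consistency_random_deletion(self):
        """Deleting years completely at random moves estimates < 3 MC SEs."""
        rng = np.random.default_rng(21)
        n, T = 1500, 8
        X, _ = design_matrices(T, 1)
        cls = rng.random(n) < 0.5
        mu = np.where(cls[:, None], (X @ [2.0, -0.2])[None, :], (X @ [9.0, 0.3])[None, :])
        Y = mu + rng.normal(0, 1.0, (n, T))
        spec = GrowthMixtureSpec(n_classes=2, degree=1, random_effects="none", n_starts=8, seed=1)
        full = fit_gmm(Y, spec)
        Ymiss = Y.copy()
        drop = rng.random((n, T)) < 0.2
        # keep at least one observed year per subject
        drop[drop.all(axis=1), 0] = False
        Ymiss[drop] = np.nan
        part = fit_gmm(Ymiss, spec)
        se_pi = np.sqrt(0.25 / n)
        assert abs(full.pi[0] - part.pi[0]) < 3 * se_pi + 0.01
        assert np.abs(full.beta - part.beta).max() < 0.1

    def test_parameter_recovery_on_generator_defaults(self, protocol_runs):
        run = protocol_runs[0]
        truth = pd.Series(run.sim.labels)
        pred = run.modal_labels
        agreement = (pred == truth.loc[pred.index]).mean()
        assert agreement >= 0.90

    def test_n_less_than_params_warns(self):
        rng = np.random.default_rng(0)
        X, _ = design_matrices(5, 1)
        Y = rng.normal(5, 1, (8, 5))  # 8 subjects vs 9 parameters
        spec = GrowthMixtureSpec(n_classes=3, degree=1, random_effects="none", n_starts=2)
        with pytest.warns(UserWarning, match="parameter count"):
            fit_gmm(Y, spec)


class TestSummaries:
    def test_bic_trivial(self):
        assert compute_bic(0.0, 0, 10) == 0.0

    def test_bic_worked_example(self):
        assert compute_bic(-100.0, 5, 326) == pytest.approx(228.9345, abs=1e-3)

    def test_bic_parameter_penalty(self):
        n = 57
        assert compute_bic(-10.0, 4, n) - compute_bic(-10.0, 3, n) == pytest.approx(np.log(n))

    def test_entropy_degenerate_is_one(self):
        P = np.eye(3)[np.array([0, 1, 2, 0])]
        assert compute_entropy(P) == pytest.approx(1.0)

    def test_entropy_uniform_is_zero(self):
        P = np.full((5, 4), 0.25)
        assert compute_entropy(P) == pytest.approx(0.0)

    def test_entropy_worked_example(self):
        P = np.array([[0.9, 0.1], [0.8, 0.2]])
        assert compute_entropy(P) == pytest.approx(0.4045, abs=1e-3)

    def test_entropy_k1_missing(self):
        assert np.isnan(compute_entropy(np.ones((5, 1))))

    def test_avg_posterior_degenerate(self):
        P = np.eye(2)[np.array([0, 1, 1])]
        np.testing.assert_allclose(avg_posterior_by_modal_class(P), [1.0, 1.0])

    def test_avg_posterior_single_subject(self):
        out = avg_posterior_by_modal_class(np.array([[0.7, 0.3]]))
        assert out[0] == pytest.approx(0.7)
        assert np.isnan(out[1])

    def test_avg_posterior_matches_bruteforce(self, rng):
        P = rng.dirichlet(np.ones(3), size=100)
        out = avg_posterior_by_modal_class(P)
        modal = P.argmax(axis=1)
        for k in range(3):
            rows = [i for i in range(100) if modal[i] == k]
            expected = np.mean([P[i, k] for i in rows]) if rows else np.nan
            if rows:
                assert out[k] == pytest.approx(expected)
            else:
                assert np.isnan(out[k])


class TestRobustSE:
    def test_intercept_only_sandwich_is_s_over_sqrt_n(self):
        rng = np.random.default_rng(4)
        n = 200
        Y = rng.normal(5.0, 2.0, (n, 1))
        fit = fit_gmm(Y, GrowthMixtureSpec(n_classes=1, degree=0, random_effects="none"))
        res = robust_standard_errors(fit, Y)
        s_mle = np.sqrt(((Y - Y.mean()) ** 2).mean())
        i_mu = res.names.index("beta[0][0]")
        assert res.se_robust[i_mu] == pytest.approx(s_mle / np.sqrt(n), rel=1e-3)

    def test_correctly_specified_robust_close_to_model(self):
        rng = np.random.default_rng(8)
        n, T = 1000, 5
        X, _ = design_matrices(T, 1)
        Y = (X @ np.array([4.0, 0.3]))[None, :] + rng.normal(0, 1.0, (n, T))
        fit = fit_gmm(Y, GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none"))
        res = robust_standard_errors(fit, Y)
        for j in range(2):  # beta coefficients
            ratio = res.se_robust[j] / res.se_model[j]
            assert 0.8 < ratio < 1.2

    def test_heteroscedastic_robust_larger(self):
        rng = np.random.default_rng(9)
        n, T = 1000, 6
        X, _ = design_matrices(T, 1)
        sd = np.linspace(0.3, 3.0, T)  # variance grows with time
        Y = (X @ np.array([4.0, 0.0]))[None, :] + rng.normal(0, 1, (n, T)) * sd[None, :]
        fit = fit_gmm(Y, GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none"))
        res = robust_standard_errors(fit, Y)
        i_slope = res.names.index("beta[0][1]")
        assert res.se_robust[i_slope] > res.se_model[i_slope]

    def test_requires_converged_fit(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(5, 1, (30, 4))
        fit = fit_gmm(Y, GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none"))
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            robust_standard_errors(fit, Y)


class TestSimulateFromFit:
    def test_masks_respected(self):
        rng = np.random.default_rng(0)
        X, _ = design_matrices(6, 1)
        Y = (X @ np.array([3.0, 0.1]))[None, :] + rng.normal(0, 1, (50, 6))
        fit = fit_gmm(Y, GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none"))
        masks = rng.random((50, 6)) > 0.3
        Yb = simulate_from_fit(fit, masks, rng)
        assert np.isnan(Yb[~masks]).all()
        assert not np.isnan(Yb[masks]).any()
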