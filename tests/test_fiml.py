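"""FIML likelihood, EM, model fitting, and standardization."""

import numpy as np
import pytest
from scipy import integrate, stats

from lcstrial.fiml import (
    MomentModel,
    em_saturated,
    extract_patterns,
    fiml_loglik,
    fit_independence,
    fit_model,
    fit_saturated,
    standardize,
)
from lcstrial.lcs import implied_moments_univariate, univariate_constraints
from lcstrial.models import UnivariateLcsModel, _chol_to_flat, _flat_to_chol
from lcstrial.simulate import univariate_paper_params


class TestFimlLoglik:
    def test_complete_data_equals_direct_normal_loglik(self, rng):
        mean = np.array([1.0, -0.5, 2.0])
        a = rng.normal(size=(3, 3))
        cov = a @ a.T + np.eye(3)
        y = rng.multivariate_normal(mean, cov, size=50)
        direct = stats.multivariate_normal(mean, cov).logpdf(y).sum()
        assert fiml_loglik(y, mean, cov) == pytest.approx(direct, abs=1e-8)

    def test_single_half_missing_record(self):
        # One record (x0=1, x1 missing) under a standard normal margin.
        y = np.array([[1.0, np.nan]])
        ll = fiml_loglik(y, np.zeros(2), np.eye(2))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5, abs=1e-10)

    def test_marginal_equals_quadrature_on_three_variable_toy(self, rng):
        mean = np.array([0.3, -0.2, 0.5])
        cov = np.array([[1.0, 0.4, 0.2], [0.4, 1.5, -0.3], [0.2, -0.3, 0.8]])
        record = np.array([0.7, np.nan, -0.4])
        ll = fiml_loglik(record[None, :], mean, cov)
        dens = stats.multivariate_normal(mean, cov)

        def full(x1):
            return dens.pdf([record[0], x1, record[2]])

        marginal, _ = integrate.quad(full, -12, 12, epsabs=1e-12)
        assert ll == pytest.approx(np.log(marginal), abs=1e-6)

    def test_empty_records_contribute_nothing(self):
        y = np.array([[1.0, 2.0], [np.nan, np.nan]])
        assert fiml_loglik(y, np.zeros(2), np.eye(2)) == pytest.approx(
            fiml_loglik(y[:1], np.zeros(2), np.eye(2))
        )

    def test_loglik_invariant_to_record_order(self, rng):
        y = rng.normal(size=(40, 3))
        y[rng.random(y.shape) < 0.3] = np.nan
        y = y[~np.isnan(y).all(axis=1)]
        mean, cov = np.zeros(3), np.eye(3) * 1.3
        perm = rng.permutation(len(y))
        assert fiml_loglik(y, mean, cov) == pytest.approx(
            fiml_loglik(y[perm], mean, cov), abs=1e-9
        )


class _SaturatedCholModel(MomentModel):
    """Direct-optimization saturated model (mean + Cholesky covariance)."""

    label = "saturated-direct"
    smooth = True

    def __init__(self, p):
        self.p = p

    def param_names(self):
        return [f"m{i}" for i in range(self.p)] + [
            f"c{i}" for i in range(self.p * (self.p + 1) // 2)
        ]

    def implied(self, theta):
        p = self.p
        L = _flat_to_chol(theta[p:], p)
        return [(theta[:p], L @ L.T)]

    def start(self, group_moments, n_used):
        mu, cov = group_moments[0]
        return np.concatenate([mu, _chol_to_flat(np.linalg.cholesky(cov))])

    # natural == working here (covariance kept in Cholesky form throughout)


class TestSaturatedAndIndependence:
    def test_em_on_complete_data_equals_sample_moments(self, rng):
        y = rng.normal(size=(60, 4))
        mu, sigma, ll, conv, _ = em_saturated(y)
        assert conv
        assert np.allclose(mu, y.mean(axis=0), atol=1e-10)
        d = y - y.mean(axis=0)
        assert np.allclose(sigma, d.T @ d / len(y), atol=1e-8)

    def test_em_agrees_with_direct_optimization_under_missingness(self, rng):
        y = rng.multivariate_normal([0, 1, -1], np.eye(3) + 0.5, size=150)
        y[rng.random(y.shape) < 0.25] = np.nan
        y = y[~np.isnan(y).all(axis=1)]
        sat = fit_saturated([y])
        direct = fit_model([y], _SaturatedCholModel(3), compute_se=False,
                           gtol=1e-9)
        assert direct.loglik == pytest.approx(sat.loglik, abs=1e-6)

    def test_reference_fit_ordering(self, default_trial):
        groups = default_trial.arm_matrices(["EPDS"])
        sat = fit_saturated(groups)
        ind = fit_independence(groups)
        model_fit = fit_model(groups, UnivariateLcsModel(group_labels=["i", "c"]),
                              compute_se=False)
        assert ind.loglik <= sat.loglik + 1e-8
        assert model_fit.loglik <= sat.loglik + 1e-8

    def test_independence_closed_form_on_complete_data(self, rng):
        y = rng.normal(size=(40, 3))
        ind = fit_independence([y])
        mu, cov = ind.group_moments[0]
        assert np.allclose(mu, y.mean(axis=0))
        assert np.allclose(np.diag(cov), y.var(axis=0))


class TestFitModel:
    def test_saturated_univariate_matches_closed_forms_exactly(self, rng):
        p = univariate_paper_params("EPDS", "intervention")
        mean, cov = implied_moments_univariate(p)
        y = rng.multivariate_normal(mean, cov, size=300)
        fit = fit_model([y], UnivariateLcsModel(n_groups=1), compute_se=False)
        x0, d = y[:, 0], y[:, 1] - y[:, 0]
        expect = {
            "mu0": x0.mean(),
            "var0": x0.var(),
            "mu_delta": d.mean(),
            "var_delta": d.var(),
            "cov0_delta": np.cov(x0, d, bias=True)[0, 1],
        }
        for name, val in zip(fit.names, fit.estimates):
            assert val == pytest.approx(expect[name], abs=1e-8)

    def test_parameter_recovery_complete_and_mcar(self, rng):
        truth = univariate_paper_params("EPDS", "intervention")
        mean, cov = implied_moments_univariate(truth)
        n = 4000
        y = rng.multivariate_normal(mean, cov, size=n)
        y_mcar = y.copy()
        y_mcar[rng.random(n) < 0.3, 1] = np.nan
        target = {
            "mu0": truth.mu0, "var0": truth.var0, "mu_delta": truth.mu_delta,
            "var_delta": truth.var_delta, "cov0_delta": truth.cov0_delta,
        }
        for data in (y, y_mcar):
            fit = fit_model([data], UnivariateLcsModel(n_groups=1))
            for name, est, se in zip(fit.names, fit.estimates, fit.se):
                assert abs(est - target[name]) < 3 * se, (name, est, se)

    def test_fiml_beats_listwise_deletion_on_precision(self, rng):
        truth = univariate_paper_params("EPDS", "intervention")
        mean, cov = implied_moments_univariate(truth)
        n = 4000
        y = rng.multivariate_normal(mean, cov, size=n)
        y[rng.random(n) < 0.3, 1] = np.nan
        fit_fiml = fit_model([y], UnivariateLcsModel(n_groups=1))
        complete_rows = y[~np.isnan(y).any(axis=1)]
        fit_lw = fit_model([complete_rows], UnivariateLcsModel(n_groups=1))
        i = fit_fiml.names.index("mu0")
        assert fit_fiml.se[i] <= fit_lw.se[i] + 1e-10

    def test_estimates_invariant_to_record_order(self, rng):
        truth = univariate_paper_params("HADS_A", "control")
        mean, cov = implied_moments_univariate(truth)
        y = rng.multivariate_normal(mean, cov, size=400)
        y[rng.random(400) < 0.4, 1] = np.nan
        fit1 = fit_model([y], UnivariateLcsModel(n_groups=1), compute_se=False)
        fit2 = fit_model([y[::-1]], UnivariateLcsModel(n_groups=1),
                         compute_se=False)
        # Identical up to optimizer tolerance (well below any SE).
        assert np.allclose(fit1.estimates, fit2.estimates, atol=1e-4)

    def test_multigroup_constrained_shares_change_parameters(self, complete_trial):
        groups = complete_trial.arm_matrices(["SCS_SF"])
        model = UnivariateLcsModel(univariate_constraints(True),
                                   group_labels=["i", "c"])
        fit = fit_model(groups, model, compute_se=False)
        est0 = model.extract(fit, "mu_delta", 0)[0]
        est1 = model.extract(fit, "mu_delta", 1)[0]
        assert est0 == est1  # one shared copy by construction


class TestStandardize:
    def test_covariance_to_correlation(self):
        # cov0_delta = -3 with Var(X0)=4, Var(D)=9 -> r = -0.5.
        model = UnivariateLcsModel(n_groups=1)
        y = np.random.default_rng(5).multivariate_normal(
            *implied_moments_univariate(
                univariate_paper_params("EPDS", "control")
            ),
            size=500,
        )
        fit = fit_model([y], model)

        def corr(theta):
            # theta: mu0, var0, mu_delta, var_delta, cov0_delta
            return np.array([theta[4] / np.sqrt(theta[1] * theta[3])])

        theta = np.array([0.0, 4.0, 0.0, 9.0, -3.0])
        assert corr(theta)[0] == pytest.approx(-0.5)
        vals, ses = standardize(fit, corr)
        assert -1 <= vals[0] <= 1
        assert ses[0] > 0

    def test_standardized_value_invariant_under_rescaling(self, rng):
        truth = univariate_paper_params("DERS_SF", "intervention")
        mean, cov = implied_moments_univariate(truth)
        y = rng.multivariate_normal(mean, cov, size=800)

        def corr(theta):
            return np.array([theta[4] / np.sqrt(theta[1] * theta[3])])

        f1 = fit_model([y], UnivariateLcsModel(n_groups=1), compute_se=False)
        f2 = fit_model([y * 10.0], UnivariateLcsModel(n_groups=1),
                       compute_se=False)
        v1, _ = standardize(f1, corr)
        v2, _ = standardize(f2, corr)
        assert v1[0] == pytest.approx(v2[0], abs=1e-6)

    def test_saturated_standardization_reproduces_sample_correlation(self, rng):
        y = rng.multivariate_normal([0, 0], [[2, 0.8], [0.8, 1]], size=600)
        fit = fit_model([y], UnivariateLcsModel(n_groups=1), compute_se=False)
        t = dict(zip(fit.names, fit.estimates))
        # Correlation of (X0, X1) implied by the saturated fit equals the
        # sample correlation.
        c01 = t["var0"] + t["cov0_delta"]
        v1 = t["var0"] + 2 * t["cov0_delta"] + t["var_delta"]
        implied_r = c01 / np.sqrt(t["var0"] * v1)
        sample_r = np.corrcoef(y.T)[0, 1]
        assert implied_r == pytest.approx(sample_r, abs=1e-7)


class TestPatterns:
    def test_patterns_partition_records(self, rng):
        y = rng.normal(size=(30, 4))
        y[rng.random(y.shape) < 0.4] = np.nan
        pats, n_empty = extract_patterns(y)
        all_rows = np.concatenate([p.rows for p in pats]) if pats else []
        assert len(all_rows) + n_empty == len(y)
        assert len(set(all_rows.tolist())) == len(all_rows)
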