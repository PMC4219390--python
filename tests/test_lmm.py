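"""Longitudinal mixed-model: designs, closed-form likelihood, recovery."""

import numpy as np
import pandas as pd
import pytest

from baselinejm.data import LongitudinalData, SchemaError
from baselinejm.lmm import (
    LinearMixedModel,
    LongitudinalParams,
    LongitudinalSpec,
    LongWorkspace,
    build_design,
    eb_posterior,
    lmm_marginal_loglik,
    trajectory,
)
from baselinejm.simulate import SimulationScenario, simulate_joint
from baselinejm.splines import place_knots


def _toy_long(times=(0.0, 1.0, 2.0), values=(1.0, 2.0, 3.0), **covs):
    df = pd.DataFrame({"id": 1, "time": times, "value": values})
    for k, v in covs.items():
        df[k] = v
    return LongitudinalData(df)


class TestDesign:
    def test_intercept_only_random_design(self):
        data = _toy_long()
        X, Z = build_design(data, LongitudinalSpec(random_structure="intercept"))
        np.testing.assert_array_equal(Z, np.ones((3, 1)))

    def test_random_slope_design_is_one_t(self):
        data = _toy_long()
        _, Z = build_design(data, LongitudinalSpec(random_structure="slope"))
        np.testing.assert_array_equal(Z, np.array([[1, 0], [1, 1], [1, 2.0]]))

    def test_column_count_with_spline_and_covariates(self):
        t = np.linspace(0, 10, 40)
        data = _toy_long(times=t, values=np.sin(t), a=1.0, b=2.0, c=3.0)
        ks = place_knots(t, df=5)
        spec = LongitudinalSpec(fixed_time_basis=ks, covariates=("a", "b", "c"))
        X, _ = build_design(data, spec)
        assert X.shape[1] == 1 + 3 + 5

    def test_missing_covariate_raises(self):
        with pytest.raises(SchemaError):
            build_design(_toy_long(), LongitudinalSpec(covariates=("bmi",)))

    def test_random_df_cannot_exceed_fixed_df(self):
        ks = place_knots(np.linspace(0, 10, 40), df=2)
        with pytest.raises(ValueError):
            LongitudinalSpec(fixed_time_basis="linear", random_structure=ks)


class TestTrajectory:
    def test_constant_trajectory(self):
        p = LongitudinalParams(beta=[1.0, 0.0], sigma_e=1.0, re_cov=np.eye(2))
        np.testing.assert_allclose(trajectory(p, [0, 0], [0, 1, 7]), 1.0)

    def test_random_intercept_slope_arithmetic(self):
        # W(t) = (b0) + (b1) t with zero fixed effects: W(3) = 2 + 0.5*3
        p = LongitudinalParams(beta=[0.0, 0.0], sigma_e=1.0, re_cov=np.eye(2))
        np.testing.assert_allclose(trajectory(p, [2.0, 0.5], [3.0]), [3.5])

    def test_spline_trajectory_two_evaluations_agree(self):
        t = np.linspace(0, 10, 50)
        ks = place_knots(t, df=3)
        spec = LongitudinalSpec(fixed_time_basis=ks, random_structure="intercept")
        beta = np.array([0.5, 1.0, -0.2, 0.05])
        p = LongitudinalParams(beta=beta, sigma_e=1.0, re_cov=[[1.0]])
        at = np.array([ks.boundary[0], *ks.interior, ks.boundary[1]])
        from baselinejm.splines import rcs_basis
        direct = beta[0] + rcs_basis(at, ks) @ beta[1:] + 0.7
        np.testing.assert_allclose(trajectory(p, [0.7], at, spec=spec), direct, atol=1e-10)

    def test_dimension_mismatch_raises(self):
        p = LongitudinalParams(beta=[0.0, 0.0], sigma_e=1.0, re_cov=np.eye(2))
        with pytest.raises(ValueError):
            trajectory(p, [1.0], [0.0])


class TestMarginalLoglik:
    def test_single_record_closed_form(self):
        # one record, residual 0, total variance 1 + 1 = 2: log N(0; 0, 2)
        data = _toy_long(times=(0.0,), values=(0.0,))
        spec = LongitudinalSpec(random_structure="intercept")
        p = LongitudinalParams(beta=[0.0, 0.0], sigma_e=1.0, re_cov=[[1.0]])
        ll = lmm_marginal_loglik(p, data, spec)
        np.testing.assert_allclose(ll, -0.5 * np.log(4 * np.pi), atol=1e-12)

    def test_invariant_to_row_and_subject_ordering(self, sim_small, rng):
        long, *_ = sim_small
        p = LongitudinalParams(beta=[0.1, -0.05], sigma_e=0.5,
                               re_cov=[[1.0, 0.0625], [0.0625, 0.0625]])
        spec = LongitudinalSpec()
        ll = lmm_marginal_loglik(p, long, spec)
        shuffled = LongitudinalData(long.df.sample(frac=1.0, random_state=3))
        np.testing.assert_allclose(lmm_marginal_loglik(p, shuffled, spec), ll, atol=1e-9)

    def test_matches_scipy_mvn_oracle(self, sim_small):
        from scipy.stats import multivariate_normal

        long, *_ = sim_small
        spec = LongitudinalSpec()
        p = LongitudinalParams(beta=[0.1, -0.05], sigma_e=0.5,
                               re_cov=[[1.0, 0.0625], [0.0625, 0.0625]])
        ll = 0.0
        for _, g in long.df.groupby("id"):
            t = g["time"].to_numpy()
            Z = np.column_stack([np.ones_like(t), t])
            V = Z @ p.re_cov @ Z.T + 0.25 * np.eye(t.size)
            mean = 0.1 - 0.05 * t
            ll += multivariate_normal(mean=mean, cov=V).logpdf(g["value"].to_numpy())
        np.testing.assert_allclose(lmm_marginal_loglik(p, long, spec), ll, atol=1e-8)

    def test_interpolation_limit_small_sigma_e(self):
        data = _toy_long(times=(0.0, 1.0, 2.0), values=(0.3, 0.9, 1.1))
        spec = LongitudinalSpec(random_structure="slope")
        p = LongitudinalParams(beta=[0.0, 0.5], sigma_e=1e-6,
                               re_cov=np.array([[4.0, 0.1], [0.1, 1.0]]))
        ws = LongWorkspace(data, spec)
        mu, _ = eb_posterior(p, ws)
        fitted = trajectory(p, mu[0], data.df["time"].to_numpy())
        # random intercept+slope cannot match 3 points exactly, but the
        # least-squares line through them is reproduced
        A = np.column_stack([np.ones(3), data.df["time"]])
        lsq = A @ np.linalg.lstsq(A, data.df["value"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fitted, lsq, atol=1e-4)


class TestFit:
    def test_recovers_generating_parameters(self):
        sc = SimulationScenario(n_subjects=2000, alpha=0.0, sigma_e=0.5,
                                admin_censor=50.0)
        long, _, truth = simulate_joint(sc, seed=5)
        fit = LinearMixedModel().fit(long)
        assert fit.converged_
        se = np.sqrt(np.diag(fit.vcov_))
        # beta0, beta1 within 3 Wald SEs of 0
        assert abs(fit.beta_[0]) < 3 * se[0]
        assert abs(fit.beta_[1]) < 3 * se[1]
        assert abs(np.log(fit.sigma_e_) - np.log(0.5)) < 3 * se[2]
        np.testing.assert_allclose(fit.re_cov_[0, 0], 1.0, atol=0.15)
        np.testing.assert_allclose(fit.re_cov_[1, 1], 0.0625, atol=0.02)

    def test_loglik_matches_statsmodels_mixedlm(self, sim_small):
        import statsmodels.formula.api as smf

        long, *_ = sim_small
        fit = LinearMixedModel().fit(long)
        md = smf.mixedlm("value ~ time", long.df, groups=long.df["id"],
                         re_formula="~time")
        sm_fit = md.fit(reml=False)
        assert abs(fit.loglik_ - sm_fit.llf) < 0.05
        np.testing.assert_allclose(fit.beta_, sm_fit.fe_params.to_numpy(), atol=0.02)
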