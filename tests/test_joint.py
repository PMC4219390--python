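"""Joint likelihood: quadrature oracles, invariances, estimation sanity."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from baselinejm.data import LongitudinalData, SurvivalData
from baselinejm.joint import JointModel, compare_models, joint_loglik
from baselinejm.lmm import LongitudinalParams, LongitudinalSpec, lmm_marginal_loglik
from baselinejm.survival import WeibullPH, _design

PARAMS = dict(beta=[0.1, -0.05], sigma_e=0.5,
              re_cov=[[1.0, 0.0625], [0.0625, 0.0625]],
              lam=0.1, gamma=1.5, phi={"trt": -0.5, "age": 0.01}, alpha=0.5)


def test_alpha_zero_reduces_to_separate_models(sim_small):
    long, surv, _ = sim_small
    params = dict(PARAMS, alpha=0.0)
    jl = joint_loglik(long, surv, params, surv_covariates=("trt", "age"))
    lml = lmm_marginal_loglik(
        LongitudinalParams(beta=params["beta"], sigma_e=params["sigma_e"],
                           re_cov=params["re_cov"]),
        long, LongitudinalSpec())
    m = WeibullPH(covariates=("trt", "age"))
    t = surv.df["time"].to_numpy()
    d = surv.df["event"].to_numpy().astype(float)
    V = _design(surv, m.covariates)
    sll = -m._negll(np.array([np.log(0.1), np.log(1.5), -0.5, 0.01]), t, d, V)
    np.testing.assert_allclose(jl, lml + sll, atol=1e-6)


def test_closed_form_cumhaz_matches_nested_quadrature(sim_small):
    """Full loglik recomputed with H from 64-point Gauss-Legendre per subject."""
    long, surv, _ = sim_small
    nodes = 25
    pkg = joint_loglik(long, surv, PARAMS, surv_covariates=("trt", "age"), nodes=nodes)

    beta = np.asarray(PARAMS["beta"])
    Sigma = np.asarray(PARAMS["re_cov"])
    se2 = PARAMS["sigma_e"] ** 2
    lam, gam, alpha = PARAMS["lam"], PARAMS["gamma"], PARAMS["alpha"]
    z, w = np.polynomial.hermite.hermgauss(nodes)
    u64, w64 = np.polynomial.legendre.leggauss(64)
    u01 = (u64 + 1) / 2  # map to [0, 1]

    sdf = surv.df.set_index("id")
    ll = 0.0
    for sid, g in long.df.groupby("id"):
        t = g["time"].to_numpy()
        y = g["value"].to_numpy()
        Z = np.column_stack([np.ones_like(t), t])
        V = Z @ Sigma @ Z.T + se2 * np.eye(t.size)
        mean = beta[0] + beta[1] * t
        ll += multivariate_normal(mean=mean, cov=V).logpdf(y)
        K = Sigma @ Z.T @ np.linalg.inv(V)
        mu_b = K @ (y - mean)
        V_b = Sigma - K @ Z @ Sigma
        tau = np.sqrt(V_b[0, 0])
        row = sdf.loc[sid]
        T, d = row["time"], row["event"]
        lp = -0.5 * row["trt"] + 0.01 * row["age"]
        b0 = mu_b[0] + np.sqrt(2) * tau * z
        eta = alpha * (beta[0] + b0) + lp
        # H by quadrature: substitute t = T u^2 so the integrand is polynomial
        tt = T * u01**2
        integrand = lam * gam * tt[None, :] ** (gam - 1) * (2 * T * u01)[None, :] \
            * np.exp(eta)[:, None]
        H = 0.5 * integrand @ w64
        fac = d * (np.log(lam * gam) + (gam - 1) * np.log(T) + eta) - H
        ll += logsumexp(fac + np.log(w) - 0.5 * np.log(np.pi))
    np.testing.assert_allclose(pkg, ll, atol=1e-8)


def test_single_subject_brute_force_grid():
    """1-D random intercept: quadrature vs dense trapezoid over b0."""
    long = LongitudinalData(pd.DataFrame({"id": [1], "time": [0.0], "value": [0.7]}))
    surv = SurvivalData(pd.DataFrame({"id": [1], "time": [2.3], "event": [1]}))
    beta0, sb, se, lam, gam, alpha = 0.2, 1.1, 0.6, 0.1, 1.5, 0.4
    params = dict(beta=[beta0, 0.0], sigma_e=se, re_cov=[[sb**2]],
                  lam=lam, gamma=gam, alpha=alpha)
    pkg = joint_loglik(long, surv, params, random_structure="intercept", nodes=25)

    b = np.linspace(-8 * sb, 8 * sb, 100_001)
    eta = alpha * (beta0 + b)
    logint = (
        -0.5 * np.log(2 * np.pi * se**2) - 0.5 * (0.7 - beta0 - b) ** 2 / se**2
        + np.log(lam * gam) + (gam - 1) * np.log(2.3) + eta
        - lam * 2.3**gam * np.exp(eta)
        - 0.5 * np.log(2 * np.pi * sb**2) - 0.5 * b**2 / sb**2
    )
    brute = logsumexp(logint) + np.log(b[1] - b[0])
    np.testing.assert_allclose(pkg, brute, atol=1e-6)


def test_quadrature_convergence_in_node_count(sim_small):
    long, surv, _ = sim_small
    lls = [joint_loglik(long, surv, PARAMS, surv_covariates=("trt", "age"), nodes=n)
           for n in (9, 15, 25)]
    per_subject = np.diff(lls) / surv.n_subjects
    assert np.all(np.abs(per_subject) < 1e-4)


def test_adaptive_agrees_with_prior_grid_quadrature(sim_small):
    long, surv, _ = sim_small
    ad = joint_loglik(long, surv, PARAMS, surv_covariates=("trt", "age"), nodes=9)
    na = joint_loglik(long, surv, PARAMS, surv_covariates=("trt", "age"),
                      nodes=41, adaptive=False)
    np.testing.assert_allclose(ad, na, atol=2e-3 * surv.n_subjects)


def test_biomarker_scale_invariance(sim_small):
    """y -> c*y with matching parameter rescaling shifts loglik by -n*log c."""
    long, surv, _ = sim_small
    c = 3.7
    scaled = LongitudinalData(long.df.assign(value=long.df["value"] * c))
    p2 = dict(PARAMS,
              beta=[PARAMS["beta"][0] * c, PARAMS["beta"][1] * c],
              sigma_e=PARAMS["sigma_e"] * c,
              re_cov=(np.asarray(PARAMS["re_cov"]) * c**2).tolist(),
              alpha=PARAMS["alpha"] / c)
    ll1 = joint_loglik(long, surv, PARAMS, surv_covariates=("trt", "age"))
    ll2 = joint_loglik(scaled, surv, p2, surv_covariates=("trt", "age"))
    np.testing.assert_allclose(ll2, ll1 - len(long) * np.log(c), atol=1e-7)


def test_sign_symmetry_of_biomarker_and_alpha(sim_small):
    long, surv, _ = sim_small
    flipped = LongitudinalData(long.df.assign(value=-long.df["value"]))
    p2 = dict(PARAMS, beta=[-PARAMS["beta"][0], -PARAMS["beta"][1]],
              alpha=-PARAMS["alpha"])
    ll1 = joint_loglik(long, surv, PARAMS, surv_covariates=("trt", "age"))
    ll2 = joint_loglik(flipped, surv, p2, surv_covariates=("trt", "age"))
    np.testing.assert_allclose(ll2, ll1, atol=1e-8)


def test_current_value_association_runs_and_nests_zero_alpha(sim_small):
    long, surv, _ = sim_small
    p0 = dict(PARAMS, alpha=0.0)
    cv = joint_loglik(long, surv, p0, surv_covariates=("trt", "age"),
                      association="current_value")
    ic = joint_loglik(long, surv, p0, surv_covariates=("trt", "age"))
    np.testing.assert_allclose(cv, ic, atol=1e-6)  # alpha=0: association irrelevant


class TestFit:
    def test_fit_recovers_association(self, joint_fit_small):
        jm = joint_fit_small
        assert jm.converged_
        assert abs(jm.alpha_ - 0.5) < 3 * jm.alpha_se_
        lo, hi = jm.alpha_ci_
        assert lo < jm.alpha_ < hi

    def test_nodes_must_be_odd(self, sim_small):
        long, surv, _ = sim_small
        with pytest.raises(ValueError):
            JointModel(nodes=8).fit(long, surv)

    def test_json_round_trip(self, joint_fit_small, sim_small, tmp_path):
        long, surv, _ = sim_small
        path = tmp_path / "fit.json"
        joint_fit_small.to_json(path)
        back = JointModel.from_json(path, long, surv)
        np.testing.assert_allclose(back.theta_, joint_fit_small.theta_)
        np.testing.assert_allclose(back.loglik_at(back.params_),
                                   joint_fit_small.loglik_, atol=1e-6)

    def test_compare_models_table(self, joint_fit_small, sim_small):
        _, surv, _ = sim_small
        from baselinejm.survival import fit_naive_baseline
        naive = fit_naive_baseline(surv, covariates=("trt", "age"))
        tab = compare_models([joint_fit_small, naive])
        # AIC/BIC recomputed from loglik and parameter count, exactly
        for _, r in tab.iterrows():
            assert r["aic"] == pytest.approx(-2 * r["loglik"] + 2 * r["n_params"])
            assert r["bic"] == pytest.approx(
                -2 * r["loglik"] + r["n_params"] * np.log(surv.n_subjects))

    def test_fpm_joint_nests_weibull_joint(self, sim_small):
        long, surv, _ = sim_small
        wb = JointModel(surv_covariates=("trt", "age"), compute_vcov=False).fit(long, surv)
        fp = JointModel(family="fpm", df=2, surv_covariates=("trt", "age"),
                        compute_vcov=False).fit(long, surv)
        assert fp.loglik_ >= wb.loglik_ - 1e-4
        assert fp.n_params_ == wb.n_params_ + 1
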