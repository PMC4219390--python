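"""Shared random-effects joint model of a longitudinal biomarker and survival.

The longitudinal submodel is the linear mixed model of :mod:`baselinejm.lmm`.
The hazard links to it through either

* the *intercept* association (primary): ``h_i(t) = h0(t) exp(alpha*(beta_0 + b_0i) + phi'v_i)``
  — the hazard depends on the subject's true (error-free) baseline biomarker
  level, so the cumulative hazard has closed form under any parametric
  baseline and the model corrects the regression-dilution bias of using the
  observed baseline value; or
* the *current value* association (secondary):
  ``h_i(t) = h0(t) exp(alpha*W_i(t) + phi'v_i)`` — the cumulative hazard then
  needs an inner Gauss–Legendre integral over ``[0, T_i]``.

Likelihood.  With ``b_i ~ MVN(0, Sigma)`` the subject contribution is

    L_i = Integral  [prod_j N(Y_ij; W_i(t_ij), sigma_e^2)]
          * h_i(T_i)^{d_i} exp(-H_i(T_i)) * MVN(b_i; 0, Sigma)  db_i.

Because the longitudinal factor is Gaussian and linear in ``b_i``, it
integrates analytically: ``L_i = f_marg(Y_i) * E[ surv_i(b_i) | Y_i ]`` where
``f_marg`` is the closed-form marginal density and the expectation is over
the subject's Gaussian empirical-Bayes posterior of ``b_i``.  The remaining
low-dimensional expectation is evaluated by Gauss–Hermite quadrature with
nodes centred and scaled at that posterior — adaptive quadrature by
construction, exact in the longitudinal direction, and reducing *exactly*
to (LMM marginal + survival log-likelihood) when ``alpha = 0``.  A
non-adaptive mode (nodes placed on the random-effects prior) is retained
for cross-checking.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .data import LongitudinalData, SurvivalData, SchemaError, validate_joint
from .lmm import (
    LinearMixedModel,
    LongitudinalParams,
    LongitudinalSpec,
    LongWorkspace,
    _group_factorise,
    _group_mean,
    chol_log_pack,
    chol_log_unpack,
    eb_posterior,
    n_chol,
)
from .splines import KnotSet, rcs_basis, rcs_derivative
from .survival import WeibullPH, FlexibleParametricPH, _design, _EXP_CLIP, standardize_map
from ._numdiff import numeric_hessian

__all__ = ["JointModel", "joint_loglik", "compare_models"]

_LOG2PI = float(np.log(2.0 * np.pi))
_Z975 = 1.959963984540054


def _gh_nodes(n: int):
    z, w = np.polynomial.hermite.hermgauss(n)
    return z, np.log(w) - 0.5 * np.log(np.pi)  # log of w/sqrt(pi)


def _product_grid(z, logw, q):
    """Tensor-product Gauss–Hermite grid over q dimensions."""
    grids = np.meshgrid(*([z] * q), indexing="ij")
    Z = np.stack([g.ravel() for g in grids], axis=-1)  # (K^q, q)
    lw = np.zeros(Z.shape[0])
    for g in np.meshgrid(*([logw] * q), indexing="ij"):
        lw = lw + g.ravel()
    return Z, lw


class JointModel(BaseEstimator):
    """Maximum-likelihood joint longitudinal–survival model.

    Parameters
    ----------
    association : {'intercept', 'current_value'}
        How the longitudinal submodel enters the hazard.
    family : {'weibull', 'fpm'}
        Baseline hazard family; 'fpm' is the flexible parametric
        (spline log cumulative hazard) model with ``df`` degrees of freedom.
    df : int
        Spline df for the fpm baseline.
    nodes : odd int >= 3
        Gauss–Hermite nodes per random-effect dimension.
    adaptive : bool
        Centre quadrature at each subject's empirical-Bayes posterior
        (default) instead of the random-effects prior.
    gl_nodes : int
        Gauss–Legendre nodes for the inner cumulative-hazard integral
        (current-value association only).
    fixed_time_df : int or None
        None for a linear fixed time trend, else spline df of time.
    random_structure : {'intercept', 'slope'}
    long_covariates, surv_covariates : sequences of column names.

    Fitted attributes (trailing underscore): ``params_`` (natural-scale
    dict), ``alpha_``, ``alpha_se_``, ``alpha_ci_``, ``loglik_``, ``vcov_``
    (estimation scale), ``theta_``, ``param_names_``, ``converged_``,
    ``aic_``, ``bic_``, ``n_subjects_``, ``n_obs_``, ``knots_`` (survival
    spline knots, fpm only).
    """

    def __init__(self, association="intercept", family="weibull", df=2,
                 nodes=9, adaptive=True, gl_nodes=15,
                 fixed_time_df=None, random_structure="slope",
                 long_covariates=(), surv_covariates=(),
                 compute_vcov=True, maxiter=1000):
        self.association = association
        self.family = family
        self.df = df
        self.nodes = nodes
        self.adaptive = adaptive
        self.gl_nodes = gl_nodes
        self.fixed_time_df = fixed_time_df
        self.random_structure = random_structure
        self.long_covariates = tuple(long_covariates)
        self.surv_covariates = tuple(surv_covariates)
        self.compute_vcov = compute_vcov
        self.maxiter = maxiter

    # ------------------------------------------------------------------ setup

    def _validate_spec(self):
        if self.association not in ("intercept", "current_value"):
            raise ValueError(f"unknown association {self.association!r}")
        if self.family not in ("weibull", "fpm"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.nodes < 3 or self.nodes % 2 == 0:
            raise ValueError("nodes must be an odd integer >= 3 (node at the mode)")

    def _setup(self, long_data, surv_data, surv_knots: KnotSet | None = None):
        self._validate_spec()
        if not isinstance(long_data, LongitudinalData):
            long_data = LongitudinalData(long_data)
        if not isinstance(surv_data, SurvivalData):
            surv_data = SurvivalData(surv_data)
        validate_joint(long_data, surv_data)

        lmm_est = LinearMixedModel(fixed_time_df=self.fixed_time_df,
                                   random_structure=self.random_structure,
                                   covariates=self.long_covariates)
        spec = lmm_est._make_spec(long_data)
        ws = LongWorkspace(long_data, spec)

        sdf = surv_data.df.set_index("id").loc[ws.subject_ids].reset_index()
        surv_ordered = SurvivalData(sdf)
        self._T = sdf["time"].to_numpy()
        self._d = sdf["event"].to_numpy().astype(float)
        self._logT = np.log(self._T)
        self._ws = ws
        self._spec = spec
        # survival covariates are standardized internally for optimisation;
        # the centring shift is absorbed by the baseline-hazard intercept
        V = _design(surv_ordered, self.surv_covariates)
        if V.size:
            vmu, vsd = V.mean(axis=0), V.std(axis=0)
            vsd = np.where(vsd > 0, vsd, 1.0)
            self._V = (V - vmu) / vsd
        else:
            vmu = vsd = np.zeros(0)
            self._V = V
        nb, q, nc, nbase, ps = self._layout()
        k = nb + 1 + nc + nbase + ps + 1
        self._A = standardize_map(vmu, vsd, nb + 1 + nc + nbase, k,
                                  absorb_idx=nb + 1 + nc)
        self._Ainv = np.linalg.inv(self._A)
        self._long = long_data
        self._surv = surv_ordered
        self._z, self._logw = _gh_nodes(self.nodes)
        if self.family == "fpm":
            if surv_knots is None:
                from .splines import place_knots
                ev = self._T[self._d > 0]
                if ev.size < self.df + 1:
                    raise SchemaError("too few events for the survival spline knots")
                surv_knots = place_knots(ev, self.df, scale="log")
            self.knots_ = surv_knots
            self._B_T = rcs_basis(self._logT, surv_knots)
            self._dB_T = rcs_derivative(self._logT, surv_knots)
        else:
            self.knots_ = None
        if self.association == "current_value":
            # inner integral H = int_0^T h; the substitution t = T u^2 removes
            # the t^(gamma-1) kink at zero, so few Legendre nodes suffice
            u, w = np.polynomial.legendre.leggauss(self.gl_nodes)
            self._gl_u = (u + 1.0) / 2.0
            self._gl_w = w / 2.0

    # -------------------------------------------------- parameter vector

    def _layout(self):
        nb = len(self._spec.beta_names)
        q = self._spec.n_random
        nc = n_chol(q)
        nbase = 2 if self.family == "weibull" else self.df + 1
        ps = len(self.surv_covariates)
        return nb, q, nc, nbase, ps

    def _param_names(self):
        nb, q, nc, nbase, ps = self._layout()
        names = list(self._spec.beta_names) + ["log_sigma_e"]
        names += [f"chol_{i}" for i in range(nc)]
        if self.family == "weibull":
            names += ["log_lambda", "log_gamma"]
        else:
            names += [f"rcs_gamma{k}" for k in range(nbase)]
        names += list(self.surv_covariates) + ["alpha"]
        return names

    def _unpack(self, theta):
        nb, q, nc, nbase, ps = self._layout()
        beta = theta[:nb]
        sigma_e = float(np.exp(theta[nb]))
        Sigma = chol_log_unpack(theta[nb + 1 : nb + 1 + nc], q)
        base = theta[nb + 1 + nc : nb + 1 + nc + nbase]
        phi = theta[nb + 1 + nc + nbase : nb + 1 + nc + nbase + ps]
        alpha = float(theta[-1])
        return beta, sigma_e, Sigma, base, phi, alpha

    def _pack(self, beta, sigma_e, Sigma, base, phi, alpha):
        return np.concatenate(
            [np.ravel(beta), [np.log(sigma_e)], chol_log_pack(np.atleast_2d(Sigma)),
             np.ravel(base), np.ravel(phi), [alpha]]
        )

    # -------------------------------------------------------- likelihood

    def _surv_logfac_intercept(self, b0, d, logT, base, lp_other, idx):
        """d*log h - H for the intercept association; b0 has node axis last."""
        eta = lp_other[:, None] + b0  # alpha*(beta0+b0) already folded into b0 arg
        if self.family == "weibull":
            loglam, loggam = base
            gam = np.exp(min(loggam, 5.0))
            logH = loglam + gam * logT[:, None] + eta
            logh = loglam + loggam + (gam - 1.0) * logT[:, None] + eta
            H = np.exp(np.minimum(logH, _EXP_CLIP))
            return d[:, None] * logh - H
        s = base[0] + self._B_T[idx] @ base[1:]
        dsdx = self._dB_T[idx] @ base[1:]
        logH = s[:, None] + eta
        H = np.exp(np.minimum(logH, _EXP_CLIP))
        safe = np.where(dsdx > 0, dsdx, np.nan)
        logh = logH + (np.log(safe) - logT)[:, None]
        out = d[:, None] * logh - H
        # events at non-monotone points: impossible under the model
        out = np.where(np.isnan(out), -1e8, out)
        return out

    def _negloglik(self, theta):
        try:
            beta, sigma_e, Sigma, base, phi, alpha = self._unpack(theta)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        if not np.all(np.isfinite(theta)):
            return 1e10
        ws = self._ws
        lp_other = (self._V @ phi if phi.size else np.zeros(self._T.size))
        ll = 0.0
        try:
            params = LongitudinalParams(beta=beta, sigma_e=sigma_e, re_cov=Sigma)
        except ValueError:
            return 1e10
        if self.adaptive:
            ll = self._loglik_adaptive(params, base, phi, alpha, lp_other)
        else:
            ll = self._loglik_prior_grid(params, base, phi, alpha, lp_other)
        return -ll if np.isfinite(ll) else 1e10

    def _loglik_adaptive(self, params, base, phi, alpha, lp_other):
        ws, spec = self._ws, self._spec
        z, logw = self._z, self._logw
        q = spec.n_random
        ll = 0.0
        for g in ws.groups:
            cf, logdet = _group_factorise(g, params.sigma_e, params.re_cov)
            from scipy.linalg import cho_solve
            R = g.Y - _group_mean(g, params.beta, ws.p_cov)
            S = cho_solve(cf, R.T)
            quad = np.einsum("im,mi->i", R, S)
            n_g = len(g.subj_idx)
            ll += -0.5 * (n_g * (g.m * _LOG2PI + logdet) + quad.sum())
            K = params.re_cov @ g.Z.T
            A = cho_solve(cf, K.T)
            mu = R @ A                      # (n_g, q) posterior means
            Vb = params.re_cov - K @ A      # (q, q) shared posterior cov
            d = self._d[g.subj_idx]
            logT = self._logT[g.subj_idx]
            lp = lp_other[g.subj_idx]
            if self.association == "intercept":
                tau = np.sqrt(max(Vb[0, 0], 1e-300))
                b0 = mu[:, 0:1] + np.sqrt(2.0) * tau * z[None, :]
                arg = alpha * (params.beta[0] + b0)
                fac = self._surv_logfac_intercept(arg, d, logT, base, lp, g.subj_idx)
                ll += logsumexp(fac + logw[None, :], axis=1).sum()
            else:
                Zq, lwq = _product_grid(z, logw, q)
                Lb = np.linalg.cholesky(Vb + 1e-12 * np.eye(q))
                b = mu[:, None, :] + np.sqrt(2.0) * Zq[None, :, :] @ Lb.T
                fac = self._surv_logfac_current(b, g, d, logT, base, lp, params, alpha)
                ll += logsumexp(fac + lwq[None, :], axis=1).sum()
        return ll

    def _surv_logfac_current(self, b, g, d, logT, base, lp_other, params, alpha):
        """Current-value association: inner Gauss–Legendre over [0, T]."""
        spec, ws = self._spec, self._ws
        T = np.exp(logT)
        n_g, K, q = b.shape
        # W at event time
        zT = spec.random_design(T)                       # (n_g, q) rows per subject
        fixT = params.beta[0] + spec.time_design(T) @ params.beta[1 + ws.p_cov :]
        if ws.p_cov:
            fixT = fixT + g.U @ params.beta[1 : 1 + ws.p_cov]
        WT = fixT[:, None] + np.einsum("iq,ikq->ik", zT, b)
        if self.family == "weibull":
            loglam, loggam = base
            gam = np.exp(min(loggam, 5.0))
            logh0_T = loglam + loggam + (gam - 1.0) * logT
        else:
            sT = base[0] + self._B_T[g.subj_idx] @ base[1:]
            dsdxT = self._dB_T[g.subj_idx] @ base[1:]
            logh0_T = sT + np.log(np.where(dsdxT > 0, dsdxT, np.nan)) - logT
        logh_T = logh0_T[:, None] + alpha * WT + lp_other[:, None]
        # inner integral H = int_0^1 h(T u^2) 2 T u du
        x = T[:, None] * self._gl_u[None, :] ** 2            # (n_g, G)
        xf = x.ravel()
        fixx = params.beta[0] + spec.time_design(xf) @ params.beta[1 + ws.p_cov :]
        fixx = fixx.reshape(n_g, -1)
        if ws.p_cov:
            fixx = fixx + (g.U @ params.beta[1 : 1 + ws.p_cov])[:, None]
        zx = spec.random_design(xf).reshape(n_g, -1, q)       # (n_g, G, q)
        Wx = fixx[:, None, :] + np.einsum("igq,ikq->ikg", zx, b)
        if self.family == "weibull":
            logh0_x = (base[0] + base[1] + (gam - 1.0) * np.log(np.maximum(xf, 1e-300))).reshape(n_g, -1)
        else:
            lx = np.log(np.maximum(xf, 1e-300))
            sx = base[0] + rcs_basis(lx, self.knots_) @ base[1:]
            dsx = rcs_derivative(lx, self.knots_) @ base[1:]
            logh0_x = (sx + np.log(np.where(dsx > 0, dsx, np.nan)) - lx).reshape(n_g, -1)
        logh_x = logh0_x[:, None, :] + alpha * Wx + lp_other[:, None, None]
        h_x = np.exp(np.minimum(logh_x, _EXP_CLIP))
        jac = 2.0 * T[:, None] * self._gl_u[None, :]          # dt/du for t = T u^2
        H = np.einsum("g,ikg->ik", self._gl_w, h_x * jac[:, None, :])
        out = d[:, None] * logh_T - H
        return np.where(np.isnan(out), -1e8, out)

    def _loglik_prior_grid(self, params, base, phi, alpha, lp_other):
        """Non-adaptive quadrature: nodes on the random-effects prior."""
        ws, spec = self._ws, self._spec
        q = spec.n_random
        Zq, lwq = _product_grid(self._z, self._logw, q)
        L = np.linalg.cholesky(params.re_cov)
        b = np.sqrt(2.0) * Zq @ L.T                      # (K, q) shared nodes
        ll = 0.0
        se2 = params.sigma_e**2
        for g in ws.groups:
            R = g.Y - _group_mean(g, params.beta, ws.p_cov)   # (n_g, m)
            Zb = b @ g.Z.T                                    # (K, m)
            dev = R[:, None, :] - Zb[None, :, :]
            longfac = -0.5 * (g.m * (_LOG2PI + 2 * np.log(params.sigma_e))
                              + np.einsum("ikm,ikm->ik", dev, dev) / se2)
            d = self._d[g.subj_idx]
            logT = self._logT[g.subj_idx]
            lp = lp_other[g.subj_idx]
            if self.association == "intercept":
                arg = np.broadcast_to(alpha * (params.beta[0] + b[:, 0])[None, :],
                                      (len(g.subj_idx), b.shape[0]))
                fac = self._surv_logfac_intercept(arg, d, logT, base, lp, g.subj_idx)
            else:
                bb = np.broadcast_to(b[None, :, :], (len(g.subj_idx),) + b.shape)
                fac = self._surv_logfac_current(bb, g, d, logT, base, lp, params, alpha)
            ll += logsumexp(longfac + fac + lwq[None, :], axis=1).sum()
        return ll

    def loglik_at(self, params: dict) -> float:
        """Joint log-likelihood at natural-scale parameters.

        ``params`` keys: ``beta``, ``sigma_e``, ``re_cov``, ``phi``,
        ``alpha``, and either (``lam``, ``gamma``) or ``spline_coefs``.
        Requires :meth:`fit` or an explicit setup to have been run.
        """
        if self.family == "weibull":
            base = np.array([np.log(params["lam"]), np.log(params["gamma"])])
        else:
            base = np.asarray(params["spline_coefs"], dtype=float)
        phi = params.get("phi", np.zeros(len(self.surv_covariates)))
        if isinstance(phi, dict):
            phi = np.array([phi[c] for c in self.surv_covariates])
        theta = self._pack(params["beta"], params["sigma_e"], params["re_cov"],
                           base, phi, params["alpha"])
        return -self._negloglik(self._Ainv @ theta)

    # --------------------------------------------------------------- fit

    def _two_stage_init(self):
        lmm = LinearMixedModel(fixed_time_df=self.fixed_time_df,
                               random_structure=self.random_structure,
                               covariates=self.long_covariates,
                               compute_vcov=False).fit(self._long, spec=self._spec)
        mu, _ = eb_posterior(lmm.params_, self._ws)
        sdf = self._surv.df.copy()
        sdf["_eb_int"] = lmm.beta_[0] + mu[:, 0]
        covs = ("_eb_int", *self.surv_covariates)
        if self.family == "weibull":
            sm = WeibullPH(covariates=covs, compute_vcov=False).fit(SurvivalData(sdf))
            base0 = np.array([np.log(sm.lambda_), np.log(sm.gamma_)])
        else:
            sm = FlexibleParametricPH(df=self.df, covariates=covs,
                                      compute_vcov=False).fit(SurvivalData(sdf))
            base0 = sm.gamma_vec_.copy()
            self.knots_ = sm.knots_
            self._B_T = rcs_basis(self._logT, self.knots_)
            self._dB_T = rcs_derivative(self._logT, self.knots_)
        phi0 = np.array([sm.coef_[c] for c in self.surv_covariates])
        alpha0 = sm.coef_["_eb_int"]
        # fold the part of the hazard intercept absorbed by alpha*beta0
        theta0 = self._pack(lmm.beta_, lmm.sigma_e_, lmm.re_cov_, base0, phi0, alpha0)
        return theta0, lmm

    def fit(self, long_data, surv_data, init: np.ndarray | None = None):
        """Maximise the joint likelihood; two-stage starting values by default."""
        self._setup(long_data, surv_data)
        if init is None:
            theta0, _ = self._two_stage_init()
        else:
            theta0 = np.asarray(init, dtype=float)
        theta0 = self._Ainv @ theta0  # optimise on the standardized scale
        f = self._negloglik
        res = minimize(f, theta0, method="L-BFGS-B",
                       options={"maxiter": 300, "ftol": 1e-8, "gtol": 1e-4})
        res2 = minimize(f, res.x, method="L-BFGS-B",
                        options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-6})
        if res2.fun <= res.fun:
            res = res2
        converged = bool(res2.success or res.success)
        if not converged:
            # one restart from a perturbed point; never silently returns
            rng = np.random.default_rng(0)
            res3 = minimize(f, res.x + 1e-3 * rng.standard_normal(res.x.size),
                            method="L-BFGS-B",
                            options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-6})
            if res3.fun < res.fun:
                res = res3
            converged = bool(res3.success)
        self.theta_ = self._A @ res.x
        self.loglik_ = -float(res.fun)
        self.converged_ = converged
        self.param_names_ = self._param_names()
        self.n_params_ = res.x.size
        self.n_subjects_ = self._ws.n_subjects
        self.n_obs_ = self._ws.n_obs
        self.aic_ = -2 * self.loglik_ + 2 * self.n_params_
        self.bic_ = -2 * self.loglik_ + self.n_params_ * np.log(self.n_subjects_)
        beta, sigma_e, Sigma, base, phi, alpha = self._unpack(self.theta_)
        self.params_ = {
            "beta": beta, "sigma_e": sigma_e, "re_cov": Sigma,
            "phi": dict(zip(self.surv_covariates, phi)), "alpha": alpha,
        }
        if self.family == "weibull":
            self.params_["lam"] = float(np.exp(base[0]))
            self.params_["gamma"] = float(np.exp(base[1]))
        else:
            self.params_["spline_coefs"] = base
        self.alpha_ = alpha
        if self.compute_vcov:
            H = numeric_hessian(f, res.x)
            try:
                self.vcov_ = self._A @ np.linalg.inv(H) @ self._A.T
                se = np.sqrt(np.maximum(np.diag(self.vcov_), 0.0))
            except np.linalg.LinAlgError:
                self.vcov_ = np.full((res.x.size,) * 2, np.nan)
                se = np.full(res.x.size, np.nan)
                self.converged_ = False
            self.se_ = dict(zip(self.param_names_, se))
            self.alpha_se_ = float(se[-1])
            self.alpha_ci_ = (alpha - _Z975 * self.alpha_se_, alpha + _Z975 * self.alpha_se_)
        return self

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.maximum(np.diag(self.vcov_), 0.0))
        return pd.DataFrame(
            {"estimate": self.theta_, "se": se,
             "ci_low": self.theta_ - _Z975 * se, "ci_high": self.theta_ + _Z975 * se},
            index=self.param_names_,
        )

    # ----------------------------------------------------- serialisation

    def to_dict(self) -> dict:
        d = {"spec": self.get_params(), "theta": self.theta_.tolist(),
             "param_names": self.param_names_, "loglik": self.loglik_,
             "converged": self.converged_, "n_subjects": self.n_subjects_,
             "n_obs": self.n_obs_,
             "vcov": self.vcov_.tolist() if hasattr(self, "vcov_") else None,
             "surv_knots": self.knots_.to_dict() if self.knots_ else None,
             "long_time_knots": (self._spec.fixed_time_basis.to_dict()
                                 if self._spec.fixed_time_basis != "linear" else None)}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict, long_data=None, surv_data=None) -> "JointModel":
        """Rebuild a fitted model; refitting is not performed.

        If the training data are supplied the internal workspace is rebuilt
        so likelihood evaluation and trajectory methods work; otherwise only
        prediction from stored parameters is available.
        """
        spec = dict(d["spec"])
        spec["long_covariates"] = tuple(spec["long_covariates"])
        spec["surv_covariates"] = tuple(spec["surv_covariates"])
        m = cls(**spec)
        m.theta_ = np.asarray(d["theta"])
        m.param_names_ = d["param_names"]
        m.loglik_ = d["loglik"]
        m.converged_ = d["converged"]
        m.n_subjects_ = d["n_subjects"]
        m.n_obs_ = d["n_obs"]
        m.knots_ = KnotSet.from_dict(d["surv_knots"]) if d.get("surv_knots") else None
        if d.get("vcov") is not None:
            m.vcov_ = np.asarray(d["vcov"])
        basis = ("linear" if d.get("long_time_knots") is None
                 else KnotSet.from_dict(d["long_time_knots"]))
        m._spec = LongitudinalSpec(fixed_time_basis=basis,
                                   random_structure=m.random_structure,
                                   covariates=m.long_covariates)
        nb = len(m._spec.beta_names)
        q = m._spec.n_random
        beta = m.theta_[:nb]
        sigma_e = float(np.exp(m.theta_[nb]))
        Sigma = chol_log_unpack(m.theta_[nb + 1 : nb + 1 + n_chol(q)], q)
        nbase = 2 if m.family == "weibull" else m.df + 1
        base = m.theta_[nb + 1 + n_chol(q) : nb + 1 + n_chol(q) + nbase]
        ps = len(m.surv_covariates)
        phi = m.theta_[nb + 1 + n_chol(q) + nbase : nb + 1 + n_chol(q) + nbase + ps]
        m.params_ = {"beta": beta, "sigma_e": sigma_e, "re_cov": Sigma,
                     "phi": dict(zip(m.surv_covariates, phi)),
                     "alpha": float(m.theta_[-1])}
        if m.family == "weibull":
            m.params_["lam"] = float(np.exp(base[0]))
            m.params_["gamma"] = float(np.exp(base[1]))
        else:
            m.params_["spline_coefs"] = base
        m.alpha_ = m.params_["alpha"]
        if hasattr(m, "vcov_"):
            se = np.sqrt(np.maximum(np.diag(m.vcov_), 0.0))
            m.alpha_se_ = float(se[-1])
            m.alpha_ci_ = (m.alpha_ - _Z975 * m.alpha_se_, m.alpha_ + _Z975 * m.alpha_se_)
        if long_data is not None and surv_data is not None:
            m._setup(long_data, surv_data, surv_knots=m.knots_)
        return m

    @classmethod
    def from_json(cls, path, long_data=None, surv_data=None) -> "JointModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), long_data, surv_data)


def joint_loglik(long_data, surv_data, params: dict, **spec_kwargs) -> float:
    """Evaluate the joint log-likelihood at given natural-scale parameters.

    ``spec_kwargs`` are :class:`JointModel` constructor arguments.
    """
    m = JointModel(**spec_kwargs)
    m._setup(long_data, surv_data, surv_knots=params.get("knots"))
    return m.loglik_at(params)


def compare_models(fits) -> pd.DataFrame:
    """AIC/BIC comparison table for fitted models sharing a dataset.

    BIC uses the number of *subjects* as the sample size.
    """
    rows = []
    for f in fits:
        rows.append({
            "model": type(f).__name__,
            "loglik": f.loglik_,
            "n_params": f.n_params_,
            "aic": -2 * f.loglik_ + 2 * f.n_params_,
            "bic": -2 * f.loglik_ + f.n_params_ * np.log(f.n_subjects_),
        })
    return pd.DataFrame(rows)
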