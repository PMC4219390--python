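"""Linear mixed-effects longitudinal submodel.

The observed biomarker for subject ``i`` at time ``t_ij`` is

    Y_ij = W_i(t_ij) + e_ij,      e_ij ~ N(0, sigma_e^2)
    W_i(t) = x_i'(t) beta + z_i'(t) b_i + u_i' delta,   b_i ~ MVN(0, Sigma)

where the fixed design contains an intercept, baseline covariates ``u_i``
and a function of time (a raw linear term or a restricted cubic spline),
and the random design contains an intercept plus optionally a linear or
spline term of time.  ``W_i`` is the error-free trajectory; ``sigma_e`` is
classical measurement-error SD.

Because everything is Gaussian the marginal likelihood is available in
closed form: ``Y_i ~ N(X_i beta_full, Z_i Sigma Z_i' + sigma_e^2 I)``.
That closed form is used (a) to fit the model by maximum likelihood, (b)
as the analytically-integrated longitudinal factor inside the joint
likelihood, and (c) for the empirical-Bayes (conditional Gaussian)
posterior of the random effects given a subject's measurements.

Subjects sharing the same visit-time pattern share the covariance matrix
``Z Sigma Z' + sigma_e^2 I``; the workspace groups subjects by pattern so
each factorisation is done once per likelihood evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .data import LongitudinalData, SchemaError
from .splines import KnotSet, place_knots, rcs_basis
from ._numdiff import numeric_hessian

__all__ = [
    "LongitudinalSpec",
    "LongitudinalParams",
    "LongWorkspace",
    "build_design",
    "trajectory",
    "lmm_marginal_loglik",
    "eb_posterior",
    "LinearMixedModel",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LongitudinalSpec:
    """Structure of the longitudinal submodel.

    fixed_time_basis : 'linear' or a KnotSet for a restricted cubic spline
        of measurement time (fixed effects).
    random_structure : 'intercept', 'slope' (random intercept + linear
        slope) or a KnotSet (random intercept + spline terms).
    covariates : names of baseline covariate columns entering the fixed
        part as main effects on the intercept.
    """

    fixed_time_basis: object = "linear"
    random_structure: object = "slope"
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        kt = self.n_fixed_time
        q = self.n_random
        if q - 1 > kt:
            raise ValueError(
                "random time basis dimension cannot exceed the fixed time basis"
            )

    @property
    def n_fixed_time(self) -> int:
        if self.fixed_time_basis == "linear":
            return 1
        return self.fixed_time_basis.df

    @property
    def n_random(self) -> int:
        """Random-effect dimension (intercept included)."""
        if self.random_structure == "intercept":
            return 1
        if self.random_structure == "slope":
            return 2
        return 1 + self.random_structure.df

    def time_design(self, t: np.ndarray) -> np.ndarray:
        if self.fixed_time_basis == "linear":
            return np.asarray(t, dtype=float).reshape(-1, 1)
        return rcs_basis(t, self.fixed_time_basis)

    def random_design(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float).ravel()
        ones = np.ones((t.size, 1))
        if self.random_structure == "intercept":
            return ones
        if self.random_structure == "slope":
            return np.hstack([ones, t.reshape(-1, 1)])
        return np.hstack([ones, rcs_basis(t, self.random_structure)])

    @property
    def beta_names(self) -> list[str]:
        names = ["intercept"] + list(self.covariates)
        if self.fixed_time_basis == "linear":
            names.append("time")
        else:
            names += [f"time_rcs{k+1}" for k in range(self.fixed_time_basis.df)]
        return names


@dataclass
class LongitudinalParams:
    """Parameters of the longitudinal submodel.

    beta : full fixed-effect vector ordered [intercept, covariates..., time terms...]
    sigma_e : residual (measurement-error) SD, > 0
    re_cov : random-effects covariance matrix Sigma, symmetric positive definite
    """

    beta: np.ndarray
    sigma_e: float
    re_cov: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.re_cov = np.atleast_2d(np.asarray(self.re_cov, dtype=float))
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        try:
            np.linalg.cholesky(self.re_cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("re_cov must be positive definite") from err


def build_design(data: LongitudinalData, spec: LongitudinalSpec):
    """Return (X, Z) fixed and random design matrices in the data's row order."""
    for c in spec.covariates:
        if c not in data.df.columns:
            raise SchemaError(f"covariate {c!r} not present in longitudinal data")
    t = data.df["time"].to_numpy()
    U = data.df[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else np.empty((len(data.df), 0))
    X = np.hstack([np.ones((len(data.df), 1)), U, spec.time_design(t)])
    Z = spec.random_design(t)
    return X, Z


def trajectory(params: LongitudinalParams, b_i, t, u_i=None, spec: LongitudinalSpec | None = None):
    """Evaluate the noiseless subject trajectory W_i(t).

    ``spec`` defaults to random intercept + slope with a linear fixed time
    term and no covariates.
    """
    if spec is None:
        spec = LongitudinalSpec()
    b_i = np.asarray(b_i, dtype=float).ravel()
    if b_i.size != spec.n_random:
        raise ValueError(f"b_i has dimension {b_i.size}, expected {spec.n_random}")
    t = np.asarray(t, dtype=float).ravel()
    p = len(spec.covariates)
    u = np.zeros(p) if u_i is None else np.asarray(u_i, dtype=float).ravel()
    if u.size != p:
        raise ValueError("covariate vector does not match spec")
    fixed = params.beta[0] + (u @ params.beta[1 : 1 + p] if p else 0.0)
    fixed = fixed + spec.time_design(t) @ params.beta[1 + p :]
    return fixed + spec.random_design(t) @ b_i


class _Group:
    """Subjects sharing one visit-time pattern."""

    __slots__ = ("subj_idx", "t", "Y", "U", "Xt", "Z", "m")

    def __init__(self, subj_idx, t, Y, U, spec: LongitudinalSpec):
        self.subj_idx = subj_idx          # (n_g,) positions in subject order
        self.t = t                        # (m,)
        self.Y = Y                        # (n_g, m)
        self.U = U                        # (n_g, p)
        self.Xt = spec.time_design(t)     # (m, kt)
        self.Z = spec.random_design(t)    # (m, q)
        self.m = t.size


class LongWorkspace:
    """Precomputed grouped designs for fast repeated likelihood evaluation."""

    def __init__(self, data: LongitudinalData, spec: LongitudinalSpec):
        for c in spec.covariates:
            if c not in data.df.columns:
                raise SchemaError(f"covariate {c!r} not present in longitudinal data")
        self.spec = spec
        df = data.df
        ids = df["id"].to_numpy()
        # subject order = order of first appearance (stable after sort by id)
        self.subject_ids, first_idx = np.unique(ids, return_index=True)
        order = np.argsort(first_idx, kind="stable")
        self.subject_ids = self.subject_ids[order]
        self.n_subjects = self.subject_ids.size
        self.n_obs = len(df)
        id_to_pos = {s: i for i, s in enumerate(self.subject_ids)}

        patterns: dict[tuple, list] = {}
        times_all = df["time"].to_numpy()
        vals_all = df["value"].to_numpy()
        p = len(spec.covariates)
        U_all = df[list(spec.covariates)].to_numpy(dtype=float) if p else np.empty((len(df), 0))
        start = 0
        for sid, grp in df.groupby("id", sort=False):
            n_i = len(grp)
            sl = slice(start, start + n_i)
            key = tuple(np.round(times_all[sl], 12))
            patterns.setdefault(key, []).append(
                (id_to_pos[sid], vals_all[sl], U_all[start])
            )
            start += n_i

        self.groups: list[_Group] = []
        for key, rows in patterns.items():
            subj_idx = np.array([r[0] for r in rows], dtype=int)
            Y = np.vstack([r[1] for r in rows])
            U = np.vstack([r[2] for r in rows]) if p else np.empty((len(rows), 0))
            self.groups.append(_Group(subj_idx, np.array(key, dtype=float), Y, U, spec))

        self.q = spec.n_random
        self.p_cov = p


def _group_mean(group: _Group, beta: np.ndarray, p: int) -> np.ndarray:
    """Fitted fixed-part mean, shape (n_g, m)."""
    mu = beta[0] + group.Xt @ beta[1 + p :]
    if p:
        return (group.U @ beta[1 : 1 + p])[:, None] + mu[None, :]
    return np.broadcast_to(mu, group.Y.shape)


def _group_factorise(group: _Group, sigma_e: float, Sigma: np.ndarray):
    V = group.Z @ Sigma @ group.Z.T + sigma_e**2 * np.eye(group.m)
    cf = cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return cf, logdet


def lmm_marginal_loglik(
    params: LongitudinalParams,
    data: LongitudinalData | LongWorkspace,
    spec: LongitudinalSpec | None = None,
) -> float:
    """Closed-form Gaussian marginal log-likelihood, summed over subjects."""
    ws = data if isinstance(data, LongWorkspace) else LongWorkspace(data, spec or LongitudinalSpec())
    ll = 0.0
    for g in ws.groups:
        cf, logdet = _group_factorise(g, params.sigma_e, params.re_cov)
        R = g.Y - _group_mean(g, params.beta, ws.p_cov)
        S = cho_solve(cf, R.T)  # (m, n_g)
        quad = np.einsum("im,mi->i", R, S)
        ll += -0.5 * (len(g.subj_idx) * (g.m * _LOG2PI + logdet) + quad.sum())
    return float(ll)


def eb_posterior(params: LongitudinalParams, ws: LongWorkspace):
    """Empirical-Bayes posterior of b_i given each subject's measurements.

    Returns ``(mu, cov)`` with ``mu`` of shape (n_subjects, q) and ``cov``
    of shape (n_subjects, q, q); the covariance is shared within a
    visit-pattern group.
    """
    q = ws.q
    mu = np.empty((ws.n_subjects, q))
    cov = np.empty((ws.n_subjects, q, q))
    for g in ws.groups:
        cf, _ = _group_factorise(g, params.sigma_e, params.re_cov)
        R = g.Y - _group_mean(g, params.beta, ws.p_cov)
        K = params.re_cov @ g.Z.T            # (q, m)
        A = cho_solve(cf, K.T)               # (m, q)
        mu[g.subj_idx] = R @ A
        cov[g.subj_idx] = params.re_cov - K @ A
    return mu, cov


# --- unconstrained parameterisation helpers (shared with the joint model) ---

def chol_log_pack(Sigma: np.ndarray) -> np.ndarray:
    """Pack an SPD matrix as its lower Cholesky factor with logged diagonal."""
    L = np.linalg.cholesky(Sigma)
    q = L.shape[0]
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def chol_log_unpack(v: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(v[k]) if i == j else v[k]
            k += 1
    return L @ L.T


def n_chol(q: int) -> int:
    return q * (q + 1) // 2


class LinearMixedModel(BaseEstimator):
    """Maximum-likelihood linear mixed model for long-format biomarker data.

    Parameters
    ----------
    fixed_time_df : int or None
        If None, a raw linear fixed time term; otherwise the df of a
        restricted cubic spline of time (knots at centiles of observed times).
    random_structure : {'intercept', 'slope'}
        Random intercept only, or random intercept + linear slope.
    covariates : sequence of str
        Baseline covariate columns (main effects on the intercept).
    compute_vcov : bool
        Whether to compute the observed-information variance matrix.

    Fitted attributes: ``beta_``, ``sigma_e_``, ``re_cov_``, ``loglik_``,
    ``vcov_`` (on the unconstrained scale), ``param_names_``, ``converged_``,
    ``spec_``, ``n_subjects_``, ``n_obs_``, ``aic_``, ``bic_``.
    """

    def __init__(self, fixed_time_df=None, random_structure="slope",
                 covariates=(), compute_vcov=True, maxiter=500):
        self.fixed_time_df = fixed_time_df
        self.random_structure = random_structure
        self.covariates = covariates
        self.compute_vcov = compute_vcov
        self.maxiter = maxiter

    # -- parameter vector layout: [beta..., log sigma_e, chol-log(Sigma)...]
    def _pack(self, params: LongitudinalParams) -> np.ndarray:
        return np.concatenate(
            [params.beta, [np.log(params.sigma_e)], chol_log_pack(params.re_cov)]
        )

    def _unpack(self, theta: np.ndarray, nb: int, q: int) -> LongitudinalParams:
        beta = theta[:nb]
        sigma_e = float(np.exp(theta[nb]))
        Sigma = chol_log_unpack(theta[nb + 1 :], q)
        return LongitudinalParams(beta=beta, sigma_e=sigma_e, re_cov=Sigma)

    def _make_spec(self, data: LongitudinalData) -> LongitudinalSpec:
        if self.fixed_time_df is None:
            basis = "linear"
        else:
            basis = place_knots(data.df["time"].to_numpy(), self.fixed_time_df)
        return LongitudinalSpec(
            fixed_time_basis=basis,
            random_structure=self.random_structure,
            covariates=tuple(self.covariates),
        )

    def fit(self, data: LongitudinalData, spec: LongitudinalSpec | None = None):
        if not isinstance(data, LongitudinalData):
            data = LongitudinalData(data)
        spec = spec or self._make_spec(data)
        ws = LongWorkspace(data, spec)
        q = ws.q
        X, _ = build_design(data, spec)
        y = data.df["value"].to_numpy()
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        s2 = max(float(np.var(resid)), 1e-4)
        Sigma0 = np.eye(q) * s2 / 2
        if q > 1:
            Sigma0[1:, 1:] *= 0.1
        start = LongitudinalParams(beta=beta0, sigma_e=np.sqrt(s2 / 2), re_cov=Sigma0)
        nb = beta0.size
        theta0 = self._pack(start)

        def negll(theta):
            try:
                p = self._unpack(theta, nb, q)
            except (ValueError, np.linalg.LinAlgError):
                return 1e10
            ll = lmm_marginal_loglik(p, ws)
            return -ll if np.isfinite(ll) else 1e10

        res = minimize(negll, theta0, method="L-BFGS-B",
                       options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-7})
        params = self._unpack(res.x, nb, q)
        self.spec_ = spec
        self.workspace_ = ws
        self.data_ = data
        self.params_ = params
        self.beta_ = params.beta
        self.sigma_e_ = params.sigma_e
        self.re_cov_ = params.re_cov
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success)
        self.theta_ = res.x
        self.n_subjects_ = ws.n_subjects
        self.n_obs_ = ws.n_obs
        self.n_params_ = res.x.size
        self.aic_ = -2 * self.loglik_ + 2 * self.n_params_
        self.bic_ = -2 * self.loglik_ + self.n_params_ * np.log(ws.n_subjects)
        self.param_names_ = (
            spec.beta_names
            + ["log_sigma_e"]
            + [f"chol_{i}" for i in range(n_chol(q))]
        )
        if self.compute_vcov:
            H = numeric_hessian(negll, res.x)
            try:
                self.vcov_ = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                self.vcov_ = np.full((res.x.size, res.x.size), np.nan)
        return self

    def posterior_random_effects(self, data: LongitudinalData | None = None):
        """Empirical-Bayes posterior means/covariances of b_i at the MLE."""
        ws = self.workspace_ if data is None else LongWorkspace(data, self.spec_)
        return eb_posterior(self.params_, ws)
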