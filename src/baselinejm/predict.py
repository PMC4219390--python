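"""Prediction from a fitted joint model.

Two prognostic outputs:

* subject-specific fitted trajectories ``W_i(t)`` at the empirical-Bayes
  posterior means of the random effects (for subjects in the training data);
* measurement-error-corrected survival curves for a *new* patient observed
  only at baseline.  The single observed value ``Y_0`` induces a Gaussian
  posterior on the patient's random intercept (the classic shrinkage
  estimator); survival is reported both as a plug-in curve at the posterior
  mean and — the default of interest — as the marginal curve
  ``E[exp(-H(t | b_0))]`` averaged over that posterior by Gauss–Hermite
  quadrature, which propagates the baseline measurement uncertainty.

For a new patient the posterior uses longitudinal information only: the
event time is unknown at prediction time, so the survival factor cannot
contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .survival import weibull_hazard_cumhaz, fpm_survival, _EXP_CLIP

__all__ = ["NewPatient", "posterior_random_effects", "predict_survival", "fitted_trajectories"]


@dataclass
class NewPatient:
    """A patient with a single baseline biomarker observation."""

    baseline_value: float
    covariates: dict = field(default_factory=dict)


def _spec_of(fit):
    return getattr(fit, "_spec", None) or fit.spec_


def _long_params(fit):
    p = fit.params_
    if isinstance(p, dict):
        return np.asarray(p["beta"]), float(p["sigma_e"]), np.atleast_2d(p["re_cov"])
    return p.beta, p.sigma_e, p.re_cov


def posterior_random_effects(fit, times, values, covariates: dict | None = None):
    """Gaussian posterior of b given a set of longitudinal records.

    ``fit`` is a fitted JointModel or LinearMixedModel; ``times``/``values``
    are the patient's measurement times and observed responses.  Returns
    ``(mean, cov)`` for the random-effect vector.  Record times outside the
    fitted time range are allowed (spline tails are linear) but warned about.
    """
    spec = _spec_of(fit)
    beta, sigma_e, Sigma = _long_params(fit)
    t = np.asarray(times, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if t.size == 0 or t.size != y.size:
        raise ValueError("need at least one (time, value) record")
    basis = spec.fixed_time_basis
    if basis != "linear" and (t.min() < basis.boundary[0] or t.max() > basis.boundary[1]):
        import warnings
        warnings.warn("record times outside the fitted spline boundary; "
                      "linear extrapolation applies", stacklevel=2)
    p = len(spec.covariates)
    u = np.array([(covariates or {})[c] for c in spec.covariates]) if p else np.zeros(0)
    mean = beta[0] + (u @ beta[1 : 1 + p] if p else 0.0) + spec.time_design(t) @ beta[1 + p :]
    r = y - mean
    Z = spec.random_design(t)
    V = Z @ Sigma @ Z.T + sigma_e**2 * np.eye(t.size)
    cf = cho_factor(V, lower=True)
    K = Sigma @ Z.T
    A = cho_solve(cf, K.T)
    return K @ cho_solve(cf, r), Sigma - K @ A


def _cumhaz(fit, t, b0, lp_other):
    """H(t | b0) for the intercept association; t may contain 0."""
    p = fit.params_
    eta = p["alpha"] * (p["beta"][0] + b0) + lp_other
    t = np.asarray(t, dtype=float)
    if fit.family == "weibull":
        _, H = weibull_hazard_cumhaz(p["lam"], p["gamma"], t, 0.0)
        return H * np.exp(np.minimum(eta, _EXP_CLIP))
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    if pos.any():
        logH, *_ = fpm_survival(p["spline_coefs"], fit.knots_, t[pos], eta)
        out[pos] = np.exp(np.minimum(logH, _EXP_CLIP))
    return out


def predict_survival(fit, patient: NewPatient, times, naive_fit=None,
                     nodes: int = 21) -> pd.DataFrame:
    """Survival curve for a baseline-only patient.

    Returns a DataFrame with columns ``time``, ``surv_plugin`` (at the
    posterior mean of b0), ``surv_marginal`` (posterior-averaged; the
    recommended curve) and, when ``naive_fit`` is given, ``surv_naive``
    from the observed-baseline comparator model.
    """
    if fit.association != "intercept":
        raise ValueError("baseline-only prediction requires the intercept association")
    if not getattr(fit, "converged_", True):
        raise RuntimeError("model did not converge; refusing to predict")
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be non-negative and non-decreasing")
    mu, cov = posterior_random_effects(fit, [0.0], [patient.baseline_value],
                                       patient.covariates)
    mu0, tau = float(mu[0]), float(np.sqrt(cov[0, 0]))
    phi = fit.params_["phi"]
    lp_other = sum(patient.covariates.get(c, 0.0) * v for c, v in phi.items())

    surv_plugin = np.exp(-_cumhaz(fit, times, mu0, lp_other))
    z, w = np.polynomial.hermite.hermgauss(nodes)
    b0_nodes = mu0 + np.sqrt(2.0) * tau * z
    S_nodes = np.exp(-np.stack([_cumhaz(fit, times, b, lp_other) for b in b0_nodes]))
    surv_marginal = (w / np.sqrt(np.pi)) @ S_nodes
    out = pd.DataFrame({"time": times, "surv_plugin": surv_plugin,
                        "surv_marginal": surv_marginal})
    if naive_fit is not None:
        covs = dict(patient.covariates)
        covs["baseline_obs"] = patient.baseline_value
        out["surv_naive"] = naive_fit.predict_survival(times, covs)
    return out


def fitted_trajectories(fit, ids, grid) -> dict:
    """Fitted trajectories W_i(t) at posterior-mean random effects.

    ``fit`` must retain its training data (a freshly fitted JointModel).
    Returns ``{id: {"fitted": DataFrame(time, value), "observed": DataFrame}}``.
    A subject id absent from the training data raises ``KeyError``.
    """
    from .lmm import eb_posterior, LongitudinalParams

    ws = fit._ws
    spec = fit._spec
    beta, sigma_e, Sigma = _long_params(fit)
    params = LongitudinalParams(beta=beta, sigma_e=sigma_e, re_cov=Sigma)
    mu, _ = eb_posterior(params, ws)
    pos = {s: i for i, s in enumerate(ws.subject_ids)}
    grid = np.asarray(grid, dtype=float)
    p = len(spec.covariates)
    out = {}
    ldf = fit._long.df
    for sid in ids:
        if sid not in pos:
            raise KeyError(f"subject {sid!r} not in the training data")
        sub = ldf[ldf["id"] == sid]
        u = sub[list(spec.covariates)].iloc[0].to_numpy(dtype=float) if p else np.zeros(0)
        fixed = beta[0] + (u @ beta[1 : 1 + p] if p else 0.0) \
            + spec.time_design(grid) @ beta[1 + p :]
        W = fixed + spec.random_design(grid) @ mu[pos[sid]]
        out[sid] = {
            "fitted": pd.DataFrame({"time": grid, "value": W}),
            "observed": sub[["time", "value"]].reset_index(drop=True),
        }
    return out
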