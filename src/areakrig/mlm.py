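"""Two-level random-intercept logistic regression with an area-level exposure.

The model links an individual binary birth outcome to individual indicator
covariates and one derived area-level exposure:

    level 1:  logit(p_ij) = beta0_j + sum_m beta_m * x_mij
    level 2:  beta0_j     = gamma00 + gamma01 * NB_RISK_j + u0_j,
              u0_j ~ N(0, sigma_u^2)

Estimation is marginal maximum likelihood: the random intercept is
integrated out per area by adaptive Gauss-Hermite quadrature (mode + curvature
rescaling, 15 nodes by default), the marginal log-likelihood is maximized by
quasi-Newton with an analytic quadrature score, and standard errors come from
the observed information (numerically differentiated score).  Wald t = est/SE
with a normal reference gives the reported p-values.

The measurement-error variant treats the exposure itself as latent,
``NB_VAR_j ~ N(NB_RISK_j, NB_VARIANCE_j)`` with the aggregated kriging
variance as NB_VARIANCE_j, and marginalizes jointly over the latent exposure
(outer Gauss-Hermite nodes) and the random intercept (inner adaptive
quadrature) — a product rule.  With all exposure variances zero it reproduces
the plug-in fit exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

DEFAULT_U_NODES = 15
DEFAULT_EXPOSURE_NODES = 9
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MLMResult:
    """Fitted two-level logistic model in Wald-table shape.

    ``params`` maps term name -> (estimate, std_error, t, p); the intercept
    term is gamma00 and the exposure term gamma01.  ``sigma_u2`` is the
    random-intercept variance (ML estimate).
    """

    params: dict[str, tuple[float, float, float, float]]
    sigma_u2: float
    loglik: float
    n_areas: int
    n_obs: int
    n_quad: int
    converged: bool
    exposure_term: str = "nb_risk"
    meta: dict = field(default_factory=dict)

    @property
    def gamma00(self) -> float:
        return self.params["intercept"][0]

    @property
    def gamma01(self) -> float:
        return self.params[self.exposure_term][0]

    def estimate(self, term: str) -> float:
        return self.params[term][0]

    def std_error(self, term: str) -> float:
        return self.params[term][1]

    def conf_int(self, term: str, level: float = 0.95):
        est, se, _, _ = self.params[term]
        zc = norm.ppf(0.5 + level / 2.0)
        return est - zc * se, est + zc * se


def _prepare(births: pd.DataFrame, nb_risk, outcome: str, covariates):
    """Sort by area, expand the per-area exposure, build the group index."""
    if outcome not in births.columns:
        raise ValueError(f"births table has no outcome column {outcome!r}")
    if "area_id" not in births.columns:
        raise ValueError("births table needs an area_id column")
    if covariates is None:
        covariates = [c for c in births.columns if c not in ("area_id", outcome)]
    if hasattr(nb_risk, "table"):  # AreaIndicators
        nb_risk = dict(zip(nb_risk.table["area_id"], nb_risk.table["value"]))
    elif isinstance(nb_risk, pd.Series):
        nb_risk = nb_risk.to_dict()
    df = births.sort_values("area_id", kind="stable").reset_index(drop=True)
    areas, area_idx = np.unique(df["area_id"].to_numpy(), return_inverse=True)
    if len(areas) < 2:
        raise ValueError("random intercept needs at least 2 areas")
    try:
        risk = np.array([float(nb_risk[a]) for a in areas])
    except KeyError as exc:
        raise ValueError(f"no exposure value for area {exc.args[0]!r}") from exc
    if not np.isfinite(risk).all():
        raise ValueError("exposure contains missing values for fitted areas")
    y = df[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; model unidentifiable")
    Xc = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    # rows are sorted by area: reduceat boundaries
    starts = np.flatnonzero(np.r_[True, np.diff(area_idx) != 0])
    return y, Xc, list(covariates), risk, area_idx, starts, areas


class _Marginal:
    """Adaptive Gauss-Hermite marginal log-likelihood and score.

    Parameters theta = (gamma00, gamma01, beta_1..beta_m, log sigma_u).
    The exposure column can be swapped per call, which is what the
    measurement-error product rule exploits.
    """

    def __init__(self, y, Xc, risk, area_idx, starts, n_nodes=DEFAULT_U_NODES):
        self.y = y
        self.Xc = Xc
        self.risk = risk
        self.area_idx = area_idx
        self.starts = starts
        self.J = len(risk)
        t, w = hermgauss(n_nodes)
        self.t = t
        self.logw = np.log(w)
        self.n_nodes = n_nodes

    def _sum_area(self, arr):
        return np.add.reduceat(arr, self.starts)

    def area_ll_score(self, theta, risk=None, want_score=True):
        """Per-area marginal log-likelihood (J,) and score (J, p)."""
        risk = self.risk if risk is None else risk
        g00, g01 = theta[0], theta[1]
        beta = theta[2:-1]
        s = theta[-1]
        sigma = np.exp(s)
        sig2 = sigma * sigma
        eta0 = g00 + g01 * risk[self.area_idx] + (self.Xc @ beta if len(beta) else 0.0)
        y = self.y

        # Laplace mode per area by Newton on f(u) = loglik_j(u) - u^2/(2 sig2)
        u = np.zeros(self.J)
        for _ in range(50):
            p = expit(eta0 + u[self.area_idx])
            grad = self._sum_area(y - p) - u / sig2
            hess = -self._sum_area(p * (1.0 - p)) - 1.0 / sig2
            step = grad / hess
            u -= step
            if np.max(np.abs(grad)) < 1e-10:
                break
        p = expit(eta0 + u[self.area_idx])
        hess = -self._sum_area(p * (1.0 - p)) - 1.0 / sig2
        tau = 1.0 / np.sqrt(-hess)

        K = self.n_nodes
        a = np.empty((K, self.J))
        resid_sums = None
        if want_score:
            p_fix = 2 + len(beta)
            sc = np.zeros((K, self.J, p_fix + 1))
        for k in range(K):
            uk = u + np.sqrt(2.0) * tau * self.t[k]
            eta = eta0 + uk[self.area_idx]
            ll_i = y * eta - np.logaddexp(0.0, eta)
            f = self._sum_area(ll_i) - uk**2 / (2.0 * sig2) - s - _LOG_SQRT_2PI
            a[k] = self.logw[k] + self.t[k] ** 2 + f
            if want_score:
                r = y - expit(eta)
                sc[k, :, 0] = self._sum_area(r)
                sc[k, :, 1] = self._sum_area(r * risk[self.area_idx])
                for m in range(len(beta)):
                    sc[k, :, 2 + m] = self._sum_area(r * self.Xc[:, m])
                sc[k, :, -1] = uk**2 / sig2 - 1.0
        amax = a.max(axis=0)
        lse = amax + np.log(np.sum(np.exp(a - amax), axis=0))
        ll_j = np.log(np.sqrt(2.0) * tau) + lse
        if not want_score:
            return ll_j, None
        omega = np.exp(a - lse)  # (K, J) posterior node weights
        score_j = np.einsum("kj,kjp->jp", omega, sc)
        return ll_j, score_j


def _optimize(nll_grad, score, x0, bounds):
    """Quasi-Newton maximization + Newton polish on the analytic score.

    Returns ``(x, H, nll, success)`` with H the numerically differentiated
    Hessian of the log-likelihood at the solution (reused for Wald SEs).
    """
    from statsmodels.tools.numdiff import approx_fprime

    res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        raise RuntimeError(
            f"marginal likelihood did not converge: {res.message} "
            f"(gradient norm {np.max(np.abs(res.jac)):.3g})")
    if np.max(np.abs(res.x[:-1])) > 30.0:
        raise RuntimeError("diverging coefficients: complete separation?")
    # Newton polish: L-BFGS-B stops within ~1e-5 of the optimum; a couple of
    # Newton steps on the analytic score pin it down to ~1e-9
    x = res.x
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    H = None
    for _ in range(5):
        s = score(x)
        H = approx_fprime(x, score, centered=True)
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(-H, s)
        except np.linalg.LinAlgError:
            break
        x_new = np.clip(x + step, lo, hi)
        if nll_grad(x_new)[0] > nll_grad(x)[0] + 1e-9:
            break  # boundary or numerics: keep the quasi-Newton point
        x = x_new
        if np.max(np.abs(step)) < 1e-10:
            break
    if H is None:
        H = approx_fprime(x, score, centered=True)
        H = 0.5 * (H + H.T)
    nll, jac = nll_grad(x)
    return x, H, nll, bool(res.success), float(np.max(np.abs(jac)))


def _wald_params(names, est, se):
    params = {}
    for name, e, s_e in zip(names, est, se):
        t = e / s_e if s_e > 0 else np.nan
        params[name] = (float(e), float(s_e), float(t), float(2.0 * norm.sf(abs(t))))
    return params


def fit_two_level_logistic(births: pd.DataFrame, nb_risk,
                           outcome: str = "LBW", covariates=None,
                           n_quad: int = DEFAULT_U_NODES,
                           start=None) -> MLMResult:
    """Marginal-ML fit of the random-intercept logistic model.

    ``nb_risk`` maps area_id -> exposure (dict, Series, or AreaIndicators).
    ``covariates`` defaults to every birth column other than ``area_id`` and
    the outcome.  ``n_quad`` adaptive Gauss-Hermite nodes per area.
    """
    if n_quad < 15:
        raise ValueError("use at least 15 quadrature nodes")
    y, Xc, cov_names, risk, area_idx, starts, areas = _prepare(
        births, nb_risk, outcome, covariates)
    marg = _Marginal(y, Xc, risk, area_idx, starts, n_nodes=n_quad)
    p_fix = 2 + Xc.shape[1]

    def nll_grad(theta):
        ll_j, sc_j = marg.area_ll_score(theta)
        return -float(ll_j.sum()), -sc_j.sum(axis=0)

    def score(theta):
        _, sc_j = marg.area_ll_score(theta)
        return sc_j.sum(axis=0)

    if start is None:
        ybar = min(max(y.mean(), 1e-4), 1 - 1e-4)
        start = np.r_[np.log(ybar / (1 - ybar)), np.zeros(p_fix - 1), np.log(0.3)]
    bounds = [(None, None)] * p_fix + [(np.log(1e-4), np.log(20.0))]
    x, H, nll, success, gnorm = _optimize(nll_grad, score,
                                          np.asarray(start, dtype=float), bounds)
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    names = ["intercept", "nb_risk"] + cov_names
    sigma_u = float(np.exp(x[-1]))
    params = _wald_params(names, x[:p_fix], se[:p_fix])
    return MLMResult(params=params, sigma_u2=sigma_u**2,
                     loglik=-float(nll), n_areas=len(areas), n_obs=len(y),
                     n_quad=n_quad, converged=success,
                     meta={"sigma_u_se_log": float(se[-1]),
                           "grad_norm": gnorm})


def fit_two_level_logistic_me(births: pd.DataFrame, risk_mean, risk_sd,
                              outcome: str = "LBW", covariates=None,
                              n_quad: int = DEFAULT_U_NODES,
                              n_exposure_nodes: int = DEFAULT_EXPOSURE_NODES,
                              start=None) -> MLMResult:
    """Measurement-error fit: latent exposure NB_VAR_j ~ N(mean_j, sd_j^2).

    Jointly marginalizes the latent exposure (outer Gauss-Hermite nodes,
    >= 9) and the random intercept (inner adaptive quadrature, >= 15 nodes)
    via a product rule.  ``risk_sd`` of zero everywhere reduces exactly to
    :func:`fit_two_level_logistic`.
    """
    if n_exposure_nodes < 9:
        raise ValueError("use at least 9 exposure quadrature nodes")
    if hasattr(risk_mean, "table"):
        tbl = risk_mean.table
        risk_mean = dict(zip(tbl["area_id"], tbl["value"]))
    if hasattr(risk_sd, "table"):
        tbl = risk_sd.table
        risk_sd = dict(zip(tbl["area_id"], tbl["se"]))
    y, Xc, cov_names, m_j, area_idx, starts, areas = _prepare(
        births, risk_mean, outcome, covariates)
    if isinstance(risk_sd, pd.Series):
        risk_sd = risk_sd.to_dict()
    if isinstance(risk_sd, dict):
        s_j = np.array([float(risk_sd[a]) for a in areas])
    else:
        s_j = np.asarray(risk_sd, dtype=float)
        if len(s_j) != len(areas):
            raise ValueError("risk_sd must align with the fitted areas")
    if np.any(s_j < 0) or not np.isfinite(s_j).all():
        raise ValueError("risk_sd must be finite and >= 0")

    marg = _Marginal(y, Xc, m_j, area_idx, starts, n_nodes=n_quad)
    p_fix = 2 + Xc.shape[1]
    tq, wq = hermgauss(n_exposure_nodes)
    logwq = np.log(wq) - 0.5 * np.log(np.pi)  # weights of N(m, s^2) quadrature
    Q = n_exposure_nodes

    def ll_score(theta, want_score=True):
        a = np.empty((Q, marg.J))
        scs = np.zeros((Q, marg.J, p_fix + 1)) if want_score else None
        for q in range(Q):
            vq = m_j + np.sqrt(2.0) * s_j * tq[q]
            ll_j, sc_j = marg.area_ll_score(theta, risk=vq, want_score=want_score)
            a[q] = logwq[q] + ll_j
            if want_score:
                scs[q] = sc_j
        amax = a.max(axis=0)
        lse = amax + np.log(np.sum(np.exp(a - amax), axis=0))
        if not want_score:
            return lse, None
        omega = np.exp(a - lse)
        return lse, np.einsum("qj,qjp->jp", omega, scs)

    def nll_grad(theta):
        ll_j, sc_j = ll_score(theta)
        return -float(ll_j.sum()), -sc_j.sum(axis=0)

    def score(theta):
        _, sc_j = ll_score(theta)
        return sc_j.sum(axis=0)

    if start is None:
        ybar = min(max(y.mean(), 1e-4), 1 - 1e-4)
        start = np.r_[np.log(ybar / (1 - ybar)), np.zeros(p_fix - 1), np.log(0.3)]
    bounds = [(None, None)] * p_fix + [(np.log(1e-4), np.log(20.0))]
    x, H, nll, success, gnorm = _optimize(nll_grad, score,
                                          np.asarray(start, dtype=float), bounds)
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    names = ["intercept", "nb_risk"] + cov_names
    sigma_u = float(np.exp(x[-1]))
    params = _wald_params(names, x[:p_fix], se[:p_fix])
    return MLMResult(params=params, sigma_u2=sigma_u**2,
                     loglik=-float(nll), n_areas=len(areas), n_obs=len(y),
                     n_quad=n_quad, converged=success,
                     meta={"n_exposure_nodes": n_exposure_nodes,
                           "grad_norm": gnorm})


def wald_table(result: MLMResult, alpha: float = 0.05) -> pd.DataFrame:
    """One row per coefficient: term, estimate, SE, t, p, significance flag."""
    rows = []
    for term, (est, se, t, p) in result.params.items():
        if se == 0 or not np.isfinite(se):
            raise ValueError(f"degenerate standard error for term {term!r}")
        rows.append({"term": term, "estimate": est, "std_error": se,
                     "t_value": t, "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows)
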