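"""Logistic regression with nested random intercepts (county within state).

The model for a binary outcome y_i with fixed covariates x_i is

    logit P(y_i = 1 | u, v) = x_i' beta + sigma_c * z_{county(i)} + sigma_s * w_{state(i)}

with z_c, w_s independent standard normals, so the county and state
random-intercept variances are sigma_c^2 and sigma_s^2.  The marginal
likelihood integrates the random effects out by a Laplace approximation:
random effects enter on the standardized scale, which keeps the
approximated log-likelihood smooth at sigma = 0 and makes the fit collapse
exactly onto ordinary logistic regression at the boundary.

Because counties are nested in states, the joint mode-finding Hessian is
block-arrow per state (a diagonal over that state's counties plus one
border row for the state effect), so Newton steps and the Laplace
log-determinant cost O(n) per iteration via Schur complements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = ["NestedLogisticFit", "fit_nested_logistic"]

_Z95 = 1.959963984540054


@dataclass
class NestedLogisticFit:
    """Maximum (Laplace) likelihood fit of the nested-intercept logistic model."""

    params: pd.Series  # fixed-effect coefficients
    cov_params: pd.DataFrame  # covariance of the fixed effects
    sigma2_county: float
    sigma2_state: float
    loglik: float
    converged: bool
    n_obs: int
    n_counties: int
    n_states: int
    boundary: dict[str, bool] = field(default_factory=dict)
    n_iter: int = 0

    def summary_table(self) -> pd.DataFrame:
        """Odds ratios with Wald 95% CIs and p-values per coefficient."""
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        beta = self.params.to_numpy()
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        return pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "or": np.exp(beta),
                "or_low": np.exp(beta - _Z95 * se),
                "or_high": np.exp(beta + _Z95 * se),
                "p": 2 * special.ndtr(-np.abs(z)),
            },
            index=self.params.index,
        )


class _LaplaceObjective:
    """Negative Laplace log-likelihood over (beta, sigma_c, sigma_s)."""

    def __init__(self, y, X, county, state, county_state):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.county = np.asarray(county, int)
        self.state = np.asarray(state, int)
        self.n_c = int(self.county.max()) + 1
        self.n_s = int(self.state.max()) + 1
        # state of each county (nesting map)
        self.county_state = np.asarray(county_state, int)
        self.z = np.zeros(self.n_c)
        self.w = np.zeros(self.n_s)
        self.n_p = self.X.shape[1]

    def _inner_newton(self, beta, sc, ss, max_iter=200, tol=1e-9):
        """Find the joint mode of the random effects given (beta, sigma)."""
        y, county, state = self.y, self.county, self.state
        cs = self.county_state
        xb = self.X @ beta  # fixed within the inner problem

        def joint(z, w):
            eta = xb + sc * z[county] + ss * w[state]
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
            return ll - 0.5 * float(z @ z) - 0.5 * float(w @ w)

        # a stale warm start in a saturated region can be worse than zero
        z, w = self.z.copy(), self.w.copy()
        f = joint(z, w)
        f_zero = joint(np.zeros(self.n_c), np.zeros(self.n_s))
        if f_zero > f:
            z, w, f = np.zeros(self.n_c), np.zeros(self.n_s), f_zero
        for it in range(max_iter):
            eta = xb + sc * z[county] + ss * w[state]
            mu = special.expit(eta)
            resid = y - mu
            wgt = mu * (1.0 - mu)
            g_z = sc * np.bincount(county, weights=resid, minlength=self.n_c) - z
            g_w = ss * np.bincount(state, weights=resid, minlength=self.n_s) - w
            gnorm = max(np.abs(g_z).max(initial=0.0), np.abs(g_w).max(initial=0.0))
            if gnorm < tol:
                break
            W_c = np.bincount(county, weights=wgt, minlength=self.n_c)
            W_s = np.bincount(state, weights=wgt, minlength=self.n_s)
            d = sc * sc * W_c + 1.0  # county diagonal of -H
            b = sc * ss * W_c  # county/state border of -H
            schur = (
                ss * ss * W_s
                + 1.0
                - np.bincount(cs, weights=b * b / d, minlength=self.n_s)
            )
            rhs_w = g_w - np.bincount(cs, weights=b * g_z / d, minlength=self.n_s)
            dw = rhs_w / schur
            dz = (g_z - b * dw[cs]) / d
            if gnorm < 1e-4:
                # inside the Newton basin: full steps, no line search (f
                # comparisons are float-limited here but the gradient is not)
                z, w = z + dz, w + dw
                continue
            step = 1.0
            improved = False
            for _ in range(25):
                f_new = joint(z + step * dz, w + step * dw)
                if f_new >= f - 1e-10:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break  # at floating-point resolution of the objective
            z, w = z + step * dz, w + step * dw
            f = f_new
        # log det(-H) at the mode, via the same Schur structure
        eta = xb + sc * z[county] + ss * w[state]
        wgt = special.expit(eta) * (1.0 - special.expit(eta))
        W_c = np.bincount(county, weights=wgt, minlength=self.n_c)
        W_s = np.bincount(state, weights=wgt, minlength=self.n_s)
        d = sc * sc * W_c + 1.0
        b = sc * ss * W_c
        schur = ss * ss * W_s + 1.0 - np.bincount(cs, weights=b * b / d, minlength=self.n_s)
        logdet = float(np.log(d).sum() + np.log(schur).sum())
        self.z, self.w = z, w  # warm start for the next evaluation
        return joint(z, w), logdet

    def loglik(self, theta) -> float:
        beta = theta[: self.n_p]
        sc, ss = abs(theta[self.n_p]), abs(theta[self.n_p + 1])
        f_mode, logdet = self._inner_newton(beta, sc, ss)
        return f_mode - 0.5 * logdet

    def __call__(self, theta) -> float:
        return -self.loglik(theta)


def _numeric_hessian(fun, x, h=1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    steps = h * np.maximum(1.0, np.abs(x))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = steps[i]
        fp[i] = fun(x + e)
        fm[i] = fun(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            e_i = np.zeros(n)
            e_j = np.zeros(n)
            e_i[i] = steps[i]
            e_j[j] = steps[j]
            fpp = fun(x + e_i + e_j)
            fmm = fun(x - e_i - e_j)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                2 * steps[i] * steps[j]
            )
    return H


def fit_nested_logistic(
    y,
    X: pd.DataFrame,
    county_ids,
    state_ids,
    start: np.ndarray | None = None,
    maxiter: int = 300,
) -> NestedLogisticFit:
    """Fit the nested random-intercept logistic model by Laplace ML.

    Parameters
    ----------
    y : binary outcome (0/1).
    X : fixed-effects design matrix (include an intercept column).
    county_ids, state_ids : cluster labels per observation; every county
        must belong to exactly one state.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    county_codes, county_uniques = pd.factorize(np.asarray(county_ids))
    state_codes, state_uniques = pd.factorize(np.asarray(state_ids))
    if len(state_uniques) < 2 or len(county_uniques) < 2:
        raise ValueError("need at least 2 states and 2 counties")
    cs_map = np.full(len(county_uniques), -1, int)
    for c, s in zip(county_codes, state_codes):
        if cs_map[c] == -1:
            cs_map[c] = s
        elif cs_map[c] != s:
            raise ValueError("county labels must nest within states")

    obj = _LaplaceObjective(y, X.to_numpy(), county_codes, state_codes, cs_map)
    n_p = X.shape[1]
    if start is None:
        # logistic fit without random effects as the fixed-effect start
        from statsmodels.api import Logit

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                beta0 = Logit(y, X.to_numpy()).fit(disp=False, maxiter=200).params
            except Exception:
                beta0 = np.zeros(n_p)
        start = np.concatenate([beta0, [0.5, 0.5]])

    bounds = [(None, None)] * n_p + [(0.0, None), (0.0, None)]
    res = optimize.minimize(
        obj,
        start,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    # boundary polish: a tiny fitted standard deviation usually marks a
    # boundary solution blurred by approximation noise (the Laplace
    # objective is itself only accurate to ~1e-3 log-likelihood units in
    # this regime), so prefer the pinned-at-zero refit unless the
    # likelihood clearly objects
    for k in (n_p, n_p + 1):
        if 0.0 < res.x[k] < 0.15:
            pinned = [(0.0, 0.0) if i == k else b for i, b in enumerate(bounds)]
            start_k = res.x.copy()
            start_k[k] = 0.0
            res_k = optimize.minimize(
                obj, start_k, method="L-BFGS-B", bounds=pinned,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            if res_k.fun <= res.fun + 1e-3:
                res = res_k
    theta = res.x
    sc, ss = float(theta[n_p]), float(theta[n_p + 1])
    boundary = {"county": sc < 1e-4, "state": ss < 1e-4}
    if any(boundary.values()):
        warnings.warn(
            "random-intercept variance at the zero boundary: "
            + ", ".join(k for k, v in boundary.items() if v),
            RuntimeWarning,
        )

    # observed-information covariance; variance rows at the boundary are dropped
    free = list(range(n_p)) + [n_p + i for i, k in enumerate(("county", "state")) if not boundary[k]]
    H = _numeric_hessian(lambda t: obj(_embed(theta, free, t)), theta[free])
    cov_free = _safe_inv(H)
    cov_beta = cov_free[:n_p, :n_p]

    return NestedLogisticFit(
        params=pd.Series(theta[:n_p], index=list(X.columns)),
        cov_params=pd.DataFrame(cov_beta, index=list(X.columns), columns=list(X.columns)),
        sigma2_county=sc**2,
        sigma2_state=ss**2,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_obs=len(y),
        n_counties=len(county_uniques),
        n_states=len(state_uniques),
        boundary=boundary,
        n_iter=int(res.nit),
    )


def _embed(theta, free, values):
    full = theta.copy()
    full[free] = values
    return full


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; using pseudo-inverse", RuntimeWarning)
        return np.linalg.pinv(H)
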