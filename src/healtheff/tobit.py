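"""Censored-normal (Tobit) regression, pooled and with random effects.

Second-stage regression of efficiency scores on covariates.  Because the
two-stage SBM score is bounded below at 0 (and super-efficiency removes the
usual upper bound at 1), least squares on the censored response is biased;
the Tobit likelihood mixes a probability mass at the censoring bound with a
normal density inside it:

    y*_it = x_it' beta + u_i + e_it,     y_it = clip(y*_it, lower, upper)
    u_i ~ N(0, sigma_u^2),  e_it ~ N(0, sigma_e^2)

The pooled model sets sigma_u = 0.  The random-effects likelihood
integrates u_i out by Gauss-Hermite quadrature.  Both are maximized with
L-BFGS-B on (beta, log sigma) and report standard errors from the inverse
observed information (numerical Hessian).  The joint significance of the
slopes is assessed by a Wald chi-square test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess

__all__ = ["CensorSpec", "TobitFit", "fit_tobit_pooled", "fit_tobit_re",
           "wald_test"]

_BOUND_EPS = 1e-10


@dataclass(frozen=True)
class CensorSpec:
    """Censoring bounds for the latent response; defaults to left
    censoring at 0 with no upper bound (super-efficiency scores exceed 1)."""

    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("censoring requires lower < upper")


@dataclass
class TobitFit:
    names: list[str]            # slope names then "_cons"
    beta: np.ndarray
    sigma_e: float
    sigma_u: float              # 0 for the pooled model
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    wald_chi2: float
    wald_df: int
    wald_p: float
    loglik: float
    n_censored: int
    converged: bool
    cov: np.ndarray             # covariance of beta (incl. intercept)
    n_obs: int = 0
    trace: list[float] = field(default_factory=list)
    se_sigma_e: float = math.nan
    se_sigma_u: float = math.nan

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table in the conventional layout
        (variable, coefficient, standard error, z, p)."""
        return pd.DataFrame({
            "variable": self.names,
            "coefficient": self.beta,
            "std_err": self.se,
            "z": self.z,
            "p": self.p,
        })


def _design(X, add_names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(float)
    else:
        mat = np.asarray(X, float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = add_names or [f"x{j+1}" for j in range(mat.shape[1])]
    if np.any(np.ptp(mat, axis=0) == 0):
        j = int(np.argmin(np.ptp(mat, axis=0)))
        raise ValueError(
            f"column {names[j]!r} is constant; the intercept is added "
            "internally — do not supply one")
    if not np.all(np.isfinite(mat)):
        raise ValueError("covariates must be finite")
    design = np.column_stack([mat, np.ones(len(mat))])
    return design, names + ["_cons"]


def _censor_masks(y, censor: CensorSpec):
    lo = y <= censor.lower + _BOUND_EPS if np.isfinite(censor.lower) \
        else np.zeros(len(y), bool)
    hi = y >= censor.upper - _BOUND_EPS if np.isfinite(censor.upper) \
        else np.zeros(len(y), bool)
    mid = ~(lo | hi)
    if not mid.any():
        raise ValueError("all observations censored: Tobit unidentified")
    if np.isfinite(censor.lower) and np.any(y < censor.lower - _BOUND_EPS):
        raise ValueError("response below the lower censoring bound")
    if np.isfinite(censor.upper) and np.any(y > censor.upper + _BOUND_EPS):
        raise ValueError("response above the upper censoring bound")
    return lo, hi, mid


def _obs_loglik(y, xb, sigma, censor, lo, hi, mid):
    """Per-observation censored-normal log-likelihood contributions."""
    ll = np.empty(len(y))
    if lo.any():
        ll[lo] = stats.norm.logcdf((censor.lower - xb[lo]) / sigma)
    if hi.any():
        ll[hi] = stats.norm.logsf((censor.upper - xb[hi]) / sigma)
    ll[mid] = stats.norm.logpdf(y[mid], loc=xb[mid], scale=sigma)
    return ll


def _start_values(y, design):
    beta0, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta0
    s0 = float(np.std(resid, ddof=design.shape[1])) or 1.0
    return beta0, s0


def _maximize(negll, theta0, bounds):
    trace: list[float] = []

    def cb(theta):
        trace.append(-negll(theta))

    res = optimize.minimize(
        negll, theta0, method="L-BFGS-B", bounds=bounds, callback=cb,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    converged = bool(res.success)
    return res, trace, converged


def _finish(names, theta_hat, negll, n_sigma, loglik, n_censored, n_obs,
            trace, converged):
    k = len(names)
    H = approx_hess(theta_hat, negll)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular information matrix") from err
    diag = np.diag(V).copy()
    diag[diag < 0] = np.nan
    se_all = np.sqrt(diag)
    beta = theta_hat[:k]
    se = se_all[:k]
    z = np.where(se > 0, beta / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    cov = V[:k, :k]
    # delta method for sigma = exp(log sigma)
    sig_se = []
    for j in range(n_sigma):
        s = math.exp(theta_hat[k + j])
        sig_se.append(s * se_all[k + j] if np.isfinite(se_all[k + j]) else math.nan)
    fit = TobitFit(
        names=names, beta=beta,
        sigma_e=math.exp(theta_hat[k + n_sigma - 1]),
        sigma_u=math.exp(theta_hat[k]) if n_sigma == 2 else 0.0,
        se=se, z=z, p=p,
        wald_chi2=math.nan, wald_df=k - 1, wald_p=math.nan,
        loglik=loglik, n_censored=n_censored, converged=converged,
        cov=cov, n_obs=n_obs, trace=trace,
        se_sigma_e=sig_se[-1],
        se_sigma_u=sig_se[0] if n_sigma == 2 else math.nan,
    )
    try:
        chi2, df, pw = wald_test(fit)
        fit.wald_chi2, fit.wald_df, fit.wald_p = chi2, df, pw
    except ValueError:
        pass
    return fit


def fit_tobit_pooled(y, X, censor: CensorSpec = CensorSpec()) -> TobitFit:
    """Pooled Tobit MLE.

    ``X`` carries the covariates only (no constant column: the intercept
    ``_cons`` is appended internally).  With zero censored observations the
    estimate coincides with least squares.  Deterministic given the data:
    starting values are the least-squares slopes and residual SD.
    """
    y = np.asarray(y, float)
    design, names = _design(X)
    lo, hi, mid = _censor_masks(y, censor)
    k = design.shape[1]

    def negll(theta):
        xb = design @ theta[:k]
        sigma = math.exp(theta[k])
        return -float(np.sum(_obs_loglik(y, xb, sigma, censor, lo, hi, mid)))

    beta0, s0 = _start_values(y, design)
    theta0 = np.concatenate([beta0, [math.log(s0)]])
    bounds = [(None, None)] * k + [(-10.0, 10.0)]
    res, trace, converged = _maximize(negll, theta0, bounds)
    return _finish(names, res.x, negll, 1, -res.fun,
                   int(lo.sum() + hi.sum()), len(y), trace, converged)


def fit_tobit_re(y, X, units, censor: CensorSpec = CensorSpec(),
                 quad_nodes: int = 12) -> TobitFit:
    """Random-effects panel Tobit MLE.

    The unit effect u_i ~ N(0, sigma_u^2) is integrated out of each unit's
    likelihood by Gauss-Hermite quadrature with ``quad_nodes`` points.  As
    sigma_u -> 0 the model reduces to the pooled fit; with a single period
    per unit sigma_u is unidentified and driven to the boundary.
    """
    if quad_nodes < 4:
        raise ValueError("quad_nodes must be >= 4")
    y = np.asarray(y, float)
    design, names = _design(X)
    units = np.asarray(units)
    lo, hi, mid = _censor_masks(y, censor)
    k = design.shape[1]
    _, unit_idx = np.unique(units, return_inverse=True)
    n_units = unit_idx.max() + 1
    nodes, weights = hermgauss(quad_nodes)
    log_w = np.log(weights) - 0.5 * math.log(math.pi)

    def negll(theta):
        beta = theta[:k]
        sigma_u = math.exp(theta[k])
        sigma_e = math.exp(theta[k + 1])
        xb = design @ beta
        # obs x nodes matrix of conditional log-likelihood contributions
        shift = math.sqrt(2.0) * sigma_u * nodes          # (K,)
        ll_nodes = np.empty((len(y), quad_nodes))
        for a in range(quad_nodes):
            ll_nodes[:, a] = _obs_loglik(y, xb + shift[a], sigma_e, censor,
                                         lo, hi, mid)
        # sum within unit, then logsumexp over nodes
        unit_ll = np.zeros((n_units, quad_nodes))
        np.add.at(unit_ll, unit_idx, ll_nodes)
        total = float(np.sum(logsumexp(unit_ll + log_w, axis=1)))
        if not np.isfinite(total):
            raise FloatingPointError(
                "quadrature overflow in the random-effects likelihood; "
                "rescale the covariates or response")
        return -total

    beta0, s0 = _start_values(y, design)
    theta0 = np.concatenate([beta0, [math.log(max(0.1 * s0, 1e-4)),
                                     math.log(s0)]])
    bounds = [(None, None)] * k + [(-8.0, 5.0), (-10.0, 10.0)]
    res, trace, converged = _maximize(negll, theta0, bounds)
    return _finish(names, res.x, negll, 2, -res.fun,
                   int(lo.sum() + hi.sum()), len(y), trace, converged)


def wald_test(fit: TobitFit, restriction: list | None = None):
    """Wald chi-square test that the restricted coefficients are jointly 0.

    ``restriction`` lists coefficient names or indices; default: every
    slope (all coefficients except the intercept).  Returns (chi2, df, p)
    with chi2 = b' V^-1 b over the restricted coordinates.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; Wald test unavailable")
    if restriction is None:
        idx = [i for i, nm in enumerate(fit.names) if nm != "_cons"]
    else:
        idx = [fit.names.index(r) if isinstance(r, str) else int(r)
               for r in restriction]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    if not np.all(np.isfinite(V)):
        raise ValueError("covariance unavailable for the restricted set")
    try:
        sol = np.linalg.solve(V, b)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular covariance in Wald test") from err
    chi2 = float(b @ sol)
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df))
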