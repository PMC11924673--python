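"""Logistic mixed-effects model with a patient-level random intercept.

Model: ``y_it ~ Bernoulli(logit^-1(b0 + b1 * x_it + u_i))`` with
``u_i ~ N(0, sigma^2)``.  The marginal likelihood integrates out each
patient's intercept with a Laplace approximation around the per-patient
posterior mode (found by a vectorised Newton iteration), and the outer
maximisation runs quasi-Newton (L-BFGS-B) on ``(b0, b1, log sigma)``.
Wald inference for the slope comes from the numerical Hessian of the
Laplace log-likelihood at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit


@dataclass
class GlmmFit:
    beta: float  # fixed-effect slope (log-odds per unit feature)
    se: float
    p_value: float
    intercept: float
    random_intercept_sd: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    converged: bool
    boundary_variance: bool = False  # sigma ~ 0

    def summary(self, feature_name: str = "feature") -> dict:
        return {
            "feature": feature_name,
            "estimate": self.beta,
            "se": self.se,
            "p_value": self.p_value,
            "aic": self.aic,
            "bic": self.bic,
            "loglik": self.loglik,
            "random_intercept_sd": self.random_intercept_sd,
            "n_obs": self.n_obs,
            "n_patients": self.n_groups,
        }

    def format_estimate(self) -> str:
        """Reporting style: "23.35 (8.7)"."""
        return f"{self.beta:.2f} ({self.se:.1f})"


def _group_layout(groups: np.ndarray) -> tuple[np.ndarray, int]:
    _, idx = np.unique(groups, return_inverse=True)
    return idx, int(idx.max()) + 1


def _inner_modes(
    eta_fixed: np.ndarray,
    y: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    sigma2: float,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group posterior modes of the random intercepts (vectorised Newton)."""
    b = np.zeros(n_groups)
    for _ in range(max_iter):
        eta = eta_fixed + b[gidx]
        p = expit(eta)
        grad = np.bincount(gidx, weights=y - p, minlength=n_groups) - b / sigma2
        w = np.bincount(gidx, weights=p * (1 - p), minlength=n_groups)
        hess = w + 1.0 / sigma2
        step = grad / hess
        b = b + step
        if np.abs(step).max() < tol:
            break
    eta = eta_fixed + b[gidx]
    p = expit(eta)
    w = np.bincount(gidx, weights=p * (1 - p), minlength=n_groups)
    return b, w


def laplace_loglik(
    params: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
) -> float:
    """Laplace-approximated marginal log-likelihood at (b0, b1, log sigma)."""
    b0, b1, log_sigma = params
    sigma2 = np.exp(2.0 * log_sigma)
    eta_fixed = b0 + b1 * x
    b, w = _inner_modes(eta_fixed, y, gidx, n_groups, sigma2)
    eta = eta_fixed + b[gidx]
    cond_ll = float((y * eta - np.logaddexp(0.0, eta)).sum())
    prior = float(-(b**2).sum() / (2 * sigma2))
    # -0.5 * sum_i log(sigma^2 * (W_i + 1/sigma^2)) = -0.5 * sum log(1 + sigma^2 W_i)
    curv = float(-0.5 * np.log1p(sigma2 * w).sum())
    return cond_ll + prior + curv


def fit_glmm_logistic(
    data: pd.DataFrame,
    feature: str = "feature_value",
    outcome: str = "lge_status",
    group: str = "patient_id",
    zscore: bool = True,
) -> GlmmFit:
    """Fit the random-intercept logistic model by Laplace-approximated ML."""
    x = data[feature].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=int)
    groups = data[group].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 patients")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if zscore:
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 0 else 1.0)
    gidx, n_groups = _group_layout(groups)

    def negll(params: np.ndarray) -> float:
        return -laplace_loglik(params, x, y, gidx, n_groups)

    # warm start from the pooled (fixed-effects) logistic fit
    from .classify import fit_logistic_univariate

    pooled = fit_logistic_univariate(x, y)
    x0 = np.array([pooled.intercept, pooled.slope, 0.0])
    res = optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        bounds=[(-30, 30), (-60, 60), (-6, 4)],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and res.fun > negll(x0):
        raise RuntimeError(f"GLMM optimizer failed: {res.message}")
    b0, b1, log_sigma = res.x
    loglik = -float(res.fun)
    sigma = float(np.exp(log_sigma))
    boundary = sigma < 1e-3

    hess = _numerical_hessian(negll, res.x)
    se = np.nan
    try:
        cov = np.linalg.inv(hess)
        if cov[1, 1] > 0:
            se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        pass
    if not np.isfinite(se):
        # boundary/singular curvature: fall back to the (b0, b1) block
        cov2 = np.linalg.inv(hess[:2, :2])
        se = float(np.sqrt(max(cov2[1, 1], 0.0)))
    from scipy.stats import norm

    z = b1 / se if se > 0 else np.inf
    p = 2 * norm.sf(abs(z))
    k = 3  # two fixed effects + one variance component
    n = len(y)
    return GlmmFit(
        beta=float(b1),
        se=se,
        p_value=float(p),
        intercept=float(b0),
        random_intercept_sd=sigma,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * np.log(n) - 2 * loglik,
        n_obs=n,
        n_groups=n_groups,
        converged=bool(res.success),
        boundary_variance=boundary,
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    return h


def longitudinal_report(fit: GlmmFit, feature_name: str) -> dict:
    """JSON-serialisable summary mirroring the reporting format."""
    rec = fit.summary(feature_name)
    rec["estimate_formatted"] = fit.format_estimate()
    return rec
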