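"""Maximum-likelihood linear mixed models with a single random intercept.

The model is y_ij = mu + beta * x_i + b_i + e_ij with b_i ~ N(0, sigma_b^2)
per group (barcode) and e_ij ~ N(0, sigma_e^2). Fitting is by full ML (not
REML) so that likelihood-ratio tests on the fixed effect are valid. The
variance ratio lambda = sigma_b^2 / sigma_e^2 is profiled out: for each
lambda the GLS fixed effects and the residual variance have closed forms, and
the profile log-likelihood is maximized over log(lambda) with an explicit
check of the lambda = 0 boundary. On balanced designs whose covariates are
constant within groups (the common case for barcode data) the ML solution is
computed exactly from the within/between sums of squares instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["MixedModelFit", "fit_random_intercept", "lrt_fixed_effect"]

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class MixedModelFit:
    """ML fit summary: intercept mu-hat, optional fixed slope, variances."""

    intercept: float
    fixed_beta: float | None
    sigma_b: float
    sigma_e: float
    loglik: float
    n_obs: int
    converged: bool


def _group_stats(y, groups):
    labels, inv = np.unique(groups, return_inverse=True)
    n_i = np.bincount(inv).astype(float)
    s_i = np.bincount(inv, weights=y)
    return labels, inv, n_i, s_i


def _profile_loglik(lam, n, n_i, s_i, q, XtX, Xty, GX):
    """Profile log-likelihood at variance ratio lam, plus GLS theta, sigma_e2."""
    w = lam / (1.0 + lam * n_i)
    A = XtX - np.einsum("i,ij,ik->jk", w, GX, GX)
    b = Xty - GX.T @ (w * s_i)
    try:
        theta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        theta = np.linalg.lstsq(A, b, rcond=None)[0]
    quad = q - np.sum(w * s_i**2)
    rss = quad - theta @ b
    rss = max(rss, n * _VAR_FLOOR)
    sigma_e2 = rss / n
    ll = -0.5 * (
        n * (_LOG2PI + 1.0 + np.log(sigma_e2)) + np.sum(np.log1p(lam * n_i))
    )
    return ll, theta, sigma_e2


def _fit_balanced(y, inv, n_groups, m, x_group):
    """Exact ML on a balanced design with group-constant covariates.

    Within-group contrasts carry sigma_e^2 only; group means carry
    (sigma_e^2 + m sigma_b^2)/m. The two likelihood pieces separate, giving
    closed-form estimates subject to the sigma_b^2 >= 0 constraint.
    """
    n = y.size
    gmeans = np.bincount(inv, weights=y) / m
    ssw = float(np.sum((y - gmeans[inv]) ** 2))
    X = np.column_stack([np.ones(n_groups)] + ([x_group] if x_group is not None else []))
    theta, *_ = np.linalg.lstsq(X, gmeans, rcond=None)
    ssb = float(np.sum((gmeans - X @ theta) ** 2))  # between groups, around fit
    if m == 1:
        # no within-group replication: sigma_b unidentifiable, collapse to OLS
        sigma_e2 = max(ssb / n, _VAR_FLOOR)
        ll = -0.5 * n * (_LOG2PI + 1.0 + np.log(sigma_e2))
        return theta, 0.0, sigma_e2, ll
    sigma_e2 = ssw / (n - n_groups)
    tau = m * ssb / n_groups  # ML of sigma_e^2 + m sigma_b^2
    if tau <= sigma_e2 or ssw <= 0.0:
        # boundary: sigma_b = 0, single pooled variance
        sigma2 = max((ssw + m * ssb) / n, _VAR_FLOOR)
        ll = -0.5 * n * (_LOG2PI + 1.0 + np.log(sigma2))
        return theta, 0.0, sigma2, ll
    sigma_b2 = (tau - sigma_e2) / m
    ll = -0.5 * (
        n * _LOG2PI
        + (n - n_groups) * np.log(max(sigma_e2, _VAR_FLOOR))
        + ssw / max(sigma_e2, _VAR_FLOOR)
        + n_groups * np.log(max(tau, _VAR_FLOOR))
        + m * ssb / max(tau, _VAR_FLOOR)
    )
    return theta, sigma_b2, sigma_e2, ll


def fit_random_intercept(values, groups, side=None) -> MixedModelFit:
    """Fit y = mu (+ beta * side) + b_group + e by maximum likelihood.

    Parameters
    ----------
    values : array-like of float
        Observations (log2 activities).
    groups : array-like
        Group label (barcode) per observation.
    side : array-like of {0, 1}, optional
        Fixed-effect covariate (e.g. allele indicator). When given, the fit
        includes a slope ``fixed_beta`` for it.

    With a single group, or when the profiled variance ratio hits zero, the
    fit degenerates gracefully to ordinary least squares (the sample mean for
    the intercept-only model).
    """
    y = np.asarray(values, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("no observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite activity values")
    labels, inv, n_i, s_i = _group_stats(y, np.asarray(groups).ravel())
    n = y.size
    n_groups = labels.size

    x = None
    if side is not None:
        x = np.asarray(side, dtype=float).ravel()
        if x.size != n:
            raise ValueError("side length mismatch")

    # detect group-constant covariate and balance for the exact path
    x_group = None
    group_constant = True
    if x is not None:
        gx_mean = np.bincount(inv, weights=x) / n_i
        group_constant = np.allclose(x, gx_mean[inv])
        if group_constant:
            x_group = gx_mean
    if n_groups == 1:
        # sigma_b unidentifiable with one barcode: OLS / sample mean
        if x is None or np.allclose(x, x[0]):
            mu = float(y.mean())
            resid = y - mu
            beta = None
        else:
            X = np.column_stack([np.ones(n), x])
            theta, *_ = np.linalg.lstsq(X, y, rcond=None)
            mu, beta = float(theta[0]), float(theta[1])
            resid = y - X @ theta
        sigma_e2 = float(np.mean(resid**2))
        ll = -0.5 * n * (_LOG2PI + 1.0 + np.log(max(sigma_e2, _VAR_FLOOR)))
        return MixedModelFit(
            mu, beta, 0.0, float(np.sqrt(sigma_e2)), float(ll), n, True
        )

    balanced = group_constant and np.all(n_i == n_i[0])
    if balanced:
        m = int(n_i[0])
        theta, sigma_b2, sigma_e2, ll = _fit_balanced(
            y, inv, n_groups, m, x_group
        )
        beta = float(theta[1]) if x is not None and theta.size > 1 else None
        return MixedModelFit(
            float(theta[0]),
            beta,
            float(np.sqrt(max(sigma_b2, 0.0))),
            float(np.sqrt(max(sigma_e2, 0.0))) if sigma_e2 > _VAR_FLOOR else 0.0,
            float(ll),
            n,
            True,
        )

    # general (unbalanced) profile-likelihood path
    if x is None:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), x])
    XtX = X.T @ X
    Xty = X.T @ y
    q = float(y @ y)
    p = X.shape[1]
    GX = np.zeros((n_groups, p))
    for j in range(p):
        GX[:, j] = np.bincount(inv, weights=X[:, j])

    def neg_ll(u):
        return -_profile_loglik(np.exp(u), n, n_i, s_i, q, XtX, Xty, GX)[0]

    ll0, theta0, sig0 = _profile_loglik(0.0, n, n_i, s_i, q, XtX, Xty, GX)
    res = optimize.minimize_scalar(
        neg_ll, bounds=(-15.0, 15.0), method="bounded",
        options={"xatol": 1e-8},
    )
    converged = bool(res.success)
    if res.success and -res.fun > ll0:
        lam = float(np.exp(res.x))
        ll, theta, sigma_e2 = _profile_loglik(
            lam, n, n_i, s_i, q, XtX, Xty, GX
        )
    else:
        lam, ll, theta, sigma_e2 = 0.0, ll0, theta0, sig0
        converged = True
    beta = float(theta[1]) if p > 1 else None
    sigma_b = float(np.sqrt(lam * sigma_e2))
    sigma_e = float(np.sqrt(sigma_e2)) if sigma_e2 > _VAR_FLOOR else 0.0
    if sigma_e == 0.0:
        sigma_b = 0.0
    return MixedModelFit(
        float(theta[0]), beta, sigma_b, sigma_e, float(ll), n, converged
    )


def lrt_fixed_effect(values, groups, side):
    """Likelihood-ratio test of the fixed effect (chi-square, 1 df).

    Fits the full model ``y ~ side + (1 | group)`` and the reduced model
    ``y ~ (1 | group)`` by ML and returns
    ``(beta_hat, p_value, full_fit, reduced_fit)``.
    """
    full = fit_random_intercept(values, groups, side=side)
    reduced = fit_random_intercept(values, groups, side=None)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df=1))
    if not (full.converged and reduced.converged):
        p = 1.0
    return full.fixed_beta, p, full, reduced
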