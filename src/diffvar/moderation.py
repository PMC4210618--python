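"""Empirical-Bayes moderation engine.

Row-wise least squares across thousands of features, moment-matching
estimation of an inverse-chi-square variance prior from the ensemble of
residual variances, shrinkage ("squeezing") of per-feature variances
toward that prior, moderated t-statistics, and Benjamini-Hochberg FDR.

The prior model: residual variances s_g^2 with d residual degrees of
freedom are scaled chi-squares around true variances sigma_g^2, and the
sigma_g^2 themselves follow a scaled inverse chi-square with
hyperparameters (d0, s0^2).  The posterior variance is the
precision-weighted blend

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the moderated t uses s~_g with d0 + d total degrees of freedom.
Hyperparameters are estimated by matching the mean and variance of
log(s_g^2) to the log of a scaled F distribution, which requires
inverting the trigamma function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import DesignSpec

logger = logging.getLogger(__name__)

__all__ = [
    "LinearFit",
    "ModerationParams",
    "fit_rowwise_lm",
    "estimate_prior",
    "trigamma_inverse",
    "squeeze_var",
    "moderated_t",
    "bh_adjust",
    "shrinkage_weight",
]

#: t with this many df is numerically normal; used to represent d0 = inf.
MAX_DF = 1e6


@dataclass
class LinearFit:
    """Per-feature ordinary least squares results under a shared design."""

    coefficients: np.ndarray  # G x p
    xtx_inv: np.ndarray  # p x p, (X'X)^-1, shared by all features
    sigma2: np.ndarray  # length G residual variances
    df_residual: float  # N - p

    @property
    def stdev_unscaled(self) -> np.ndarray:
        """sqrt of diag((X'X)^-1): unscaled coefficient standard deviations."""
        return np.sqrt(np.diag(self.xtx_inv))


@dataclass
class ModerationParams:
    """Variance-prior hyperparameters.

    ``d0`` is the prior degrees of freedom (np.inf allowed; 0 means "no
    prior information", i.e. no shrinkage — used as the single-feature
    fallback).  ``s0_sq`` is the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


def fit_rowwise_lm(values: np.ndarray, design: DesignSpec | np.ndarray) -> LinearFit:
    """Fit the same linear model independently to every feature (row).

    Returns coefficients, residual variances ``sigma2 = RSS / (N - p)``
    and the shared unscaled covariance ``(X'X)^-1``.
    """
    X = design.design if isinstance(design, DesignSpec) else np.asarray(design, float)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError(f"matrix has {Y.shape[1]} samples but design has {n} rows")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    q, r = np.linalg.qr(X)
    # beta' = R^-1 Q' Y'
    coef = np.linalg.solve(r, q.T @ Y.T).T
    resid = Y - coef @ X.T
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("ij,ij->i", resid, resid) / df
    r_inv = np.linalg.inv(r)
    return LinearFit(coefficients=coef, xtx_inv=r_inv @ r_inv.T, sigma2=sigma2, df_residual=float(df))


def trigamma_inverse(x: float, rtol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve psi'(y) = x for y > 0.

    The trigamma function is positive, strictly decreasing and convex on
    (0, inf), so Newton iteration from the asymptotic inverse y ~ 1/x
    converges; a bisection fallback guards pathological starts.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:  # psi'(y) ~ 1/y^2 as y -> 0
        return 1.0 / np.sqrt(x)
    if x < 1e-6:  # psi'(y) ~ 1/y as y -> inf
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y += step
        if y <= 0:
            break
        if abs(step) < rtol * y:
            return float(y)
    # bisection fallback on the monotone-decreasing trigamma
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if polygamma(1, mid) > x:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + rtol:
            break
    return float(np.sqrt(lo * hi))


def estimate_prior(sigma2: np.ndarray, df: float) -> ModerationParams:
    """Estimate (d0, s0^2) from the ensemble of residual variances.

    Moment-matching on the log scale: with z_g = log(s_g^2),
    e_g = z_g - psi(d/2) + log(d/2) is an unbiased estimate of
    log(sigma_g^2); its excess variance over psi'(d/2) identifies d0 via
    psi'(d0/2) = var(e) - psi'(d/2), and s0^2 follows from the mean.
    Zero variances carry no log-scale information and are excluded
    (counted and logged); they are still squeezed and tested downstream.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if s2.ndim != 1 or s2.size < 2:
        raise ValueError("need at least two residual variances")
    if np.any(s2 < 0):
        raise ValueError("negative residual variance")
    ok = s2 > 0
    n_zero = int((~ok).sum())
    if n_zero:
        logger.info("estimate_prior: excluding %d zero variances from moment matching", n_zero)
    s2 = s2[ok]
    if s2.size == 0:
        raise ValueError("all residual variances are zero: no variance information")
    if s2.size == 1:
        raise ValueError("fewer than two positive variances: prior not estimable")
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    m = float(e.mean())
    v = float(e.var(ddof=1))
    evar = v - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(m + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(m))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def squeeze_var(sigma2: np.ndarray, df: float, params: ModerationParams) -> np.ndarray:
    """Posterior variances: precision-weighted blend of s_g^2 and s0^2."""
    s2 = np.asarray(sigma2, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s0_sq)
    if params.d0 == 0:
        return s2.copy()
    return (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)


def shrinkage_weight(d0: float, df: float) -> float:
    """Weight d0/(d0+d) placed on the prior variance in the blend."""
    if np.isinf(d0):
        return 1.0
    return d0 / (d0 + df)


def moderated_t(
    fit: LinearFit,
    params: ModerationParams,
    coef: int | np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Moderated t-statistics for one contrast.

    Returns ``(t, df_total, p)`` where p is the two-sided tail of the t
    distribution with ``df_total = d0 + d`` degrees of freedom (capped at
    a large finite value, beyond which t is numerically normal).
    """
    p_dim = fit.coefficients.shape[1]
    if np.isscalar(coef) or isinstance(coef, (int, np.integer)):
        c = np.zeros(p_dim)
        c[int(coef)] = 1.0
    else:
        c = np.asarray(coef, dtype=float)
    estimate = fit.coefficients @ c
    var_unscaled = float(c @ fit.xtx_inv @ c)
    s2_post = squeeze_var(fit.sigma2, fit.df_residual, params)
    se = np.sqrt(s2_post * var_unscaled)
    df_total = float(min(params.d0 + fit.df_residual, MAX_DF))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, estimate / np.where(se > 0, se, 1.0), 0.0)
    zero_se = se == 0
    if np.any(zero_se):
        n_deg = int(zero_se.sum())
        logger.info("moderated_t: %d features with zero posterior variance", n_deg)
        t = np.where(zero_se & (estimate != 0), np.sign(estimate) * np.inf, t)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.where(zero_se & (estimate != 0), 0.0, pvals)
    pvals = np.where(zero_se & (estimate == 0), 1.0, pvals)
    return t, df_total, np.clip(pvals, 0.0, 1.0)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
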