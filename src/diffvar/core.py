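"""The DiffVar test and its companion differential-methylation test.

Differential variability (DV) asks whether the within-group spread of a
feature differs between groups, irrespective of group means.  The test
is a Levene-type construction made robust and high-dimensional:

1. fit the mean model and take residuals r_gj = M_gj - fitted;
2. form leverage-corrected deviations z_gj = |r_gj| / (1 + h_j) (or
   r_gj^2 / (1 + h_j) for squared deviations), where h_j is the hat
   leverage of sample j.  For a group-means design h_j = 1/n_k, so the
   factor is exactly n_k / (n_k + 1), correcting for unequal group sizes;
3. test the group difference of mean deviations with an empirical-Bayes
   moderated t and report Benjamini-Hochberg FDRs.

Working on absolute deviations rather than variances is what confers
robustness to single-sample outliers.  The test operates on M values;
beta-scale inputs are logit-transformed automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DesignSpec, MethylMatrix
from .moderation import (
    ModerationParams,
    bh_adjust,
    estimate_prior,
    fit_rowwise_lm,
    moderated_t,
)
from .transforms import beta_to_m, m_to_beta

logger = logging.getLogger(__name__)

__all__ = [
    "DeviationMatrix",
    "compute_deviations",
    "diffvar",
    "diffvar_pvalues",
    "diff_methylation",
    "variability_ratio",
    "significant_dv",
    "significant_dm",
    "dm_dv_overlap",
]


@dataclass
class DeviationMatrix:
    """Leverage-corrected deviations z_gj from the fitted mean model."""

    values: np.ndarray  # G x N, >= 0
    method: str  # "abs" or "sq"
    source_design: DesignSpec
    leverage_factor: np.ndarray  # length N, 1/(1+h_j)


def _as_m_values(matrix: MethylMatrix) -> MethylMatrix:
    if matrix.scale == "beta":
        logger.info("beta-scale input: applying logit transform to M values")
        return beta_to_m(matrix)
    return matrix


def _hat_leverage(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return np.einsum("ij,ij->i", q, q)


def compute_deviations(
    values: np.ndarray, design: DesignSpec, method: str = "abs"
) -> DeviationMatrix:
    """Absolute or squared residuals from the mean model, scaled by 1/(1+h).

    Samples with leverage h_j = 1 (e.g. a group of size one) contribute
    identically-zero residuals and make spread unestimable; they raise.
    """
    if method not in ("abs", "sq"):
        raise ValueError("method must be 'abs' or 'sq'")
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    X = design.design
    h = _hat_leverage(X)
    if np.any(h >= 1.0 - 1e-10):
        raise ValueError(
            "a sample has leverage 1 (singleton group or saturated design); "
            "deviations are identically zero there"
        )
    lev = 1.0 / (1.0 + h)
    fit = fit_rowwise_lm(Y, design)
    resid = Y - fit.coefficients @ X.T
    z = np.abs(resid) if method == "abs" else resid**2
    z = z * lev  # broadcast over features
    return DeviationMatrix(values=z, method=method, source_design=design, leverage_factor=lev)


def _moderated_pipeline(
    values: np.ndarray,
    design: DesignSpec,
    prior: ModerationParams | None,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Shared fit -> prior -> squeeze -> t -> BH chain.

    Returns (effect, t, df_total, p, adj_p).  ``prior`` overrides the
    ensemble estimate; for a single feature the fallback is d0 = 0
    (no shrinkage: the classical t).
    """
    fit = fit_rowwise_lm(values, design)
    if prior is None:
        if fit.sigma2.size < 2:
            prior = ModerationParams(d0=0.0, s0_sq=float(max(fit.sigma2[0], 1.0)))
        else:
            prior = estimate_prior(fit.sigma2, fit.df_residual)
    contrast = design.contrast_vector()
    effect = fit.coefficients @ contrast
    t, df_total, p = moderated_t(fit, prior, contrast)
    return effect, t, df_total, p, bh_adjust(p)


def variability_ratio(
    values: np.ndarray, group_masks: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature max/min ratio of the two group sample variances of M values.

    Returns ``(ratio, direction, variances)`` where direction names the
    more-variable group per feature and ``variances`` is a G x K array in
    group order.  Features where both variances are zero get ratio 1.
    """
    names = list(group_masks)
    if len(names) != 2:
        raise ValueError("variability_ratio requires exactly two groups")
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    variances = np.column_stack([Y[:, m].var(axis=1, ddof=1) for m in group_masks.values()])
    v1, v2 = variances[:, 0], variances[:, 1]
    hi = np.maximum(v1, v2)
    lo = np.minimum(v1, v2)
    both_zero = hi == 0
    if np.any(both_zero):
        logger.info("variability_ratio: %d features with both variances zero (ratio=1)", int(both_zero.sum()))
    with np.errstate(divide="ignore"):
        ratio = np.where(both_zero, 1.0, hi / np.where(lo > 0, lo, np.nan))
    ratio = np.where(np.isnan(ratio) & ~both_zero, np.inf, ratio)
    direction = np.where(v2 > v1, names[1], names[0])
    return ratio, direction, variances


def diffvar(
    matrix: MethylMatrix,
    design: DesignSpec,
    method: str = "abs",
    prior: ModerationParams | None = None,
) -> pd.DataFrame:
    """Test every feature for differential variability.

    Returns a table indexed by probe with columns ``effect`` (difference
    of mean leverage-corrected deviations under the tested contrast),
    ``t``, ``df_total``, ``p_value``, ``adj_p_value``, per-group M-value
    variances ``var_<group>``, and ``var_ratio`` (max/min, direction in
    ``more_variable_in``) when the design carries two groups.
    """
    mm = _as_m_values(matrix)
    if design.sample_ids is not None:
        design = design.aligned_to(mm.sample_ids)
    dev = compute_deviations(mm.values, design, method=method)
    effect, t, df_total, p, adj = _moderated_pipeline(dev.values, design, prior)
    out = pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "df_total": df_total,
            "p_value": p,
            "adj_p_value": adj,
        },
        index=pd.Index(mm.probe_ids, name="probe_id"),
    )
    if design.groups is not None and len(design.group_names) == 2:
        masks = design.group_masks()
        ratio, direction, variances = variability_ratio(mm.values, masks)
        for k, name in enumerate(masks):
            out[f"var_{name}"] = variances[:, k]
        out["var_ratio"] = ratio
        out["more_variable_in"] = direction
    return out


def diffvar_pvalues(
    values: np.ndarray, design: DesignSpec, method: str = "abs"
) -> np.ndarray:
    """Raw DiffVar p-values on an M-value array (fast path for simulations)."""
    dev = compute_deviations(values, design, method=method)
    return _moderated_pipeline_nobh(dev.values, design)[3]


def _moderated_pipeline_nobh(values, design):
    fit = fit_rowwise_lm(values, design)
    prior = estimate_prior(fit.sigma2, fit.df_residual)
    contrast = design.contrast_vector()
    effect = fit.coefficients @ contrast
    t, df_total, p = moderated_t(fit, prior, contrast)
    return effect, t, df_total, p


def diff_methylation(
    matrix: MethylMatrix,
    design: DesignSpec,
    prior: ModerationParams | None = None,
) -> pd.DataFrame:
    """Moderated-t test of group mean differences on the M scale.

    ``delta_beta`` reports the difference of group mean beta values (the
    interpretable proportion scale) for the two-group case.
    """
    mm = _as_m_values(matrix)
    if design.sample_ids is not None:
        design = design.aligned_to(mm.sample_ids)
    effect, t, df_total, p, adj = _moderated_pipeline(mm.values, design, prior)
    out = pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "df_total": df_total,
            "p_value": p,
            "adj_p_value": adj,
        },
        index=pd.Index(mm.probe_ids, name="probe_id"),
    )
    if design.groups is not None and len(design.group_names) == 2:
        beta = m_to_beta(mm).values
        masks = design.group_masks()
        means = [beta[:, m].mean(axis=1) for m in masks.values()]
        out["delta_beta"] = means[1] - means[0]
    return out


def significant_dv(
    result: pd.DataFrame, fdr: float = 0.05, ratio: float = 5.0
) -> pd.DataFrame:
    """Significant DV features: adj_p < fdr and variability ratio >= ratio.

    The returned frame carries the direction counts in ``.attrs["direction_counts"]``.
    """
    if len(result) == 0:
        out = result.copy()
        out.attrs["direction_counts"] = {}
        return out
    keep = (result["adj_p_value"] < fdr) & (result["var_ratio"] >= ratio)
    out = result[keep].copy()
    counts = out["more_variable_in"].value_counts().to_dict() if len(out) else {}
    out.attrs["direction_counts"] = counts
    return out


def significant_dm(
    result: pd.DataFrame, fdr: float = 0.05, min_delta_beta: float = 0.1
) -> pd.DataFrame:
    """Significant DM features: adj_p < fdr and |delta beta| >= min_delta_beta."""
    if len(result) == 0:
        return result.copy()
    keep = (result["adj_p_value"] < fdr) & (result["delta_beta"].abs() >= min_delta_beta)
    return result[keep].copy()


def dm_dv_overlap(
    dm_ranked: list[str],
    dv_ranked: list[str],
    top_n: int,
    n_random: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cumulative overlap of two feature rankings, with a random baseline.

    At each rank r = 1..top_n, counts |top-r(DM) ∩ top-r(DV)|.  The
    baseline is the median of the same curve over ``n_random`` pairs of
    random orderings of the shared feature universe; its expectation at
    rank r is approximately r^2 / U for a universe of size U.
    """
    universe = list(dict.fromkeys(dm_ranked)) if set(dm_ranked) == set(dv_ranked) else sorted(set(dm_ranked) | set(dv_ranked))
    u = len(universe)
    if top_n > u:
        raise ValueError(f"top_n={top_n} exceeds universe size {u}")
    rng = rng or np.random.default_rng()

    def curve(a: list[str], b: list[str]) -> np.ndarray:
        pos_b = {f: i for i, f in enumerate(b[:top_n])}
        counts = np.zeros(top_n, dtype=int)
        for r, f in enumerate(a[:top_n]):
            if f in pos_b:
                counts[max(r, pos_b[f]):] += 1
        return counts

    observed = curve(list(dm_ranked), list(dv_ranked))
    arr = np.asarray(universe, dtype=object)
    baselines = np.empty((n_random, top_n), dtype=int)
    for i in range(n_random):
        a = rng.permutation(arr)[:top_n].tolist()
        b = rng.permutation(arr)[:top_n].tolist()
        baselines[i] = curve(a, b)
    return pd.DataFrame(
        {
            "rank": np.arange(1, top_n + 1),
            "overlap": observed,
            "random_median": np.median(baselines, axis=0),
        }
    )
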