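"""Classical equality-of-variance tests used as comparison baselines.

Both the F test (ratio of two group sample variances) and Bartlett's
test are exact under normality but notoriously sensitive to outliers:
a single aberrant sample inflates one group's variance estimate and
drives the statistic.  They are implemented vectorised across features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .moderation import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["f_test", "bartlett_test", "f_test_pvalues", "bartlett_pvalues"]


def _group_stats(values: np.ndarray, groups: np.ndarray) -> tuple[list[str], list[np.ndarray]]:
    labels = np.asarray(groups)
    names = list(dict.fromkeys(labels.tolist()))
    cols = [np.flatnonzero(labels == name) for name in names]
    for name, idx in zip(names, cols):
        if idx.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    return names, cols


def f_test_pvalues(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided variance-ratio F test.

    Returns (F, p) with F = s1^2/s2^2 in first-appearance group order and
    p = 2 * min(P(F <= f), P(F >= f)) on (n1-1, n2-1) df, capped at 1.
    """
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    names, cols = _group_stats(Y, groups)
    if len(names) != 2:
        raise ValueError("F test requires exactly two groups")
    v1 = Y[:, cols[0]].var(axis=1, ddof=1)
    v2 = Y[:, cols[1]].var(axis=1, ddof=1)
    d1, d2 = cols[0].size - 1, cols[1].size - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = v1 / v2
    zero_den = v2 == 0
    if np.any(zero_den & (v1 > 0)):
        logger.info("f_test: %d features with zero denominator variance (p=0)", int((zero_den & (v1 > 0)).sum()))
    f = np.where(zero_den & (v1 > 0), np.inf, f)
    f = np.where(zero_den & (v1 == 0), 1.0, f)
    cdf = stats.f.cdf(f, d1, d2)
    sf = stats.f.sf(f, d1, d2)
    p = np.minimum(2.0 * np.minimum(cdf, sf), 1.0)
    p = np.where(zero_den & (v1 > 0), 0.0, p)
    p = np.where(zero_den & (v1 == 0), 1.0, p)
    return f, p


def bartlett_pvalues(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Bartlett test across K >= 2 groups.

    T = [(N-K) ln(s_p^2) - sum_k (n_k-1) ln(s_k^2)] / C with the usual
    Bartlett correction C; p is the upper chi-square tail on K-1 df (the
    statistic is non-negative and one-sided by construction).
    """
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    names, cols = _group_stats(Y, groups)
    k = len(names)
    nk = np.array([c.size for c in cols])
    n = nk.sum()
    vars_k = np.column_stack([Y[:, c].var(axis=1, ddof=1) for c in cols])
    pooled = (vars_k * (nk - 1)).sum(axis=1) / (n - k)
    correction = 1.0 + (np.sum(1.0 / (nk - 1)) - 1.0 / (n - k)) / (3.0 * (k - 1))
    zero_var = (vars_k == 0).any(axis=1)
    if np.any(zero_var):
        logger.info("bartlett_test: %d features with a zero group variance (T=inf, p=0)", int(zero_var.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = ((n - k) * np.log(pooled) - ((nk - 1) * np.log(vars_k)).sum(axis=1)) / correction
    t_stat = np.where(zero_var, np.inf, t_stat)
    # all groups constant and equal -> pooled = 0 too; treat as no evidence
    all_zero = (vars_k == 0).all(axis=1) & (pooled == 0)
    t_stat = np.where(all_zero, np.inf, t_stat)
    p = stats.chi2.sf(t_stat, k - 1)
    return t_stat, p


def _result_table(
    probe_ids: list[str], stat_name: str, stat: np.ndarray, p: np.ndarray
) -> pd.DataFrame:
    return pd.DataFrame(
        {stat_name: stat, "p_value": p, "adj_p_value": bh_adjust(p)},
        index=pd.Index(probe_ids, name="probe_id"),
    )


def f_test(matrix, groups) -> pd.DataFrame:
    """F test result table for a MethylMatrix (M scale) and group labels."""
    f, p = f_test_pvalues(matrix.values, np.asarray(groups))
    return _result_table(matrix.probe_ids, "F", f, p)


def bartlett_test(matrix, groups) -> pd.DataFrame:
    """Bartlett test result table for a MethylMatrix (M scale) and group labels."""
    t_stat, p = bartlett_pvalues(matrix.values, np.asarray(groups))
    return _result_table(matrix.probe_ids, "T", t_stat, p)
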