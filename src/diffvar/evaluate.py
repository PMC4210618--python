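"""Evaluation metrics for simulation benchmarks.

Type-I error is tallied on raw p-values at nominal cutoffs (the median
across replicate simulations is the headline number; the mean and
standard deviation are reported for diagnostics).  FDR and power are
tallied on BH-adjusted p-values at a nominal FDR cutoff.  ROC points and
cumulative outlier-ranking curves characterise how each test orders
truly differentially variable versus contaminated-null features.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .moderation import bh_adjust

__all__ = [
    "type1_error",
    "fdr_power",
    "roc_points",
    "roc_auc",
    "outlier_rank_curve",
]


def type1_error(
    replicates: Iterable[tuple[np.ndarray, np.ndarray]],
    nominal: Sequence[float] = (0.001, 0.01, 0.05, 0.1),
) -> pd.DataFrame:
    """Median (and mean, sd) proportion of null-feature raw p <= cutoff.

    ``replicates`` yields (p_values, null_mask) pairs, one per simulated
    dataset; truly differentially variable features must be masked out
    by the caller (outlier-bearing nulls remain nulls).
    """
    levels = np.asarray(nominal, dtype=float)
    rates = []
    for p, null_mask in replicates:
        p = np.asarray(p, float)[np.asarray(null_mask, bool)]
        if p.size == 0:
            raise ValueError("replicate has no null features")
        rates.append([(p <= a).mean() for a in levels])
    if not rates:
        raise ValueError("empty battery of replicates")
    arr = np.asarray(rates)
    return pd.DataFrame(
        {
            "nominal": levels,
            "median": np.median(arr, axis=0),
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.nan,
            "n_reps": arr.shape[0],
        }
    )


def fdr_power(
    p: np.ndarray, is_dv: np.ndarray, fdr: float = 0.05
) -> tuple[float, float, int]:
    """Observed FDR, power and discovery count at a BH cutoff.

    Discoveries are features with BH-adjusted p <= fdr; observed FDR is
    false/total (0 when nothing is discovered); power is true
    discoveries over the number of truly DV features (NaN when none
    exist).
    """
    p = np.asarray(p, float)
    is_dv = np.asarray(is_dv, bool)
    adj = bh_adjust(p)
    disc = adj <= fdr
    n_disc = int(disc.sum())
    n_false = int((disc & ~is_dv).sum())
    n_true = n_disc - n_false
    obs_fdr = n_false / n_disc if n_disc else 0.0
    n_dv = int(is_dv.sum())
    power = n_true / n_dv if n_dv else float("nan")
    return obs_fdr, power, n_disc


def roc_points(p: np.ndarray, is_dv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve from ranking features by ascending p-value.

    Ties are broken by stable input order.  Outlier-bearing null
    features count as negatives: ranking them highly costs false-positive
    rate.  Returns (FPR, TPR) including the implicit (0, 0) start.
    """
    p = np.asarray(p, float)
    is_dv = np.asarray(is_dv, bool)
    n_pos = int(is_dv.sum())
    n_neg = int((~is_dv).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one DV and one null feature")
    order = np.argsort(p, kind="stable")
    tp = np.concatenate([[0], np.cumsum(is_dv[order])])
    fp = np.concatenate([[0], np.cumsum(~is_dv[order])])
    return fp / n_neg, tp / n_pos


def roc_auc(p: np.ndarray, is_dv: np.ndarray) -> float:
    """Area under the ROC curve (trapezoid over the ranked points)."""
    fpr, tpr = roc_points(p, is_dv)
    return float(np.trapezoid(tpr, fpr))


def outlier_rank_curve(
    p: np.ndarray, has_outlier: np.ndarray, top_k: int
) -> np.ndarray:
    """Cumulative count of outlier-flagged features among the top r by p.

    Returns counts for r = 1..top_k (stable tie-break on input order).
    """
    p = np.asarray(p, float)
    flags = np.asarray(has_outlier, bool)
    if top_k > p.size:
        raise ValueError("top_k exceeds the number of features")
    order = np.argsort(p, kind="stable")
    return np.cumsum(flags[order])[:top_k]
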