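"""Hierarchical simulation engine for differential-variability benchmarks.

The generative model mimics a two-group methylation M-value experiment:

* a true variance per feature is drawn from a scaled inverse chi-square,
  sigma^2 = d0 * s0^2 / chi2_{d0}, with prior degrees of freedom d0 = 20
  and prior scale s0^2 = 0.64 by default (slightly more variable than
  hyperparameters estimated from large 450k cancer cohorts);
* half the features are "methylated" (mean M = +2) and half
  "unmethylated" (mean M = -2), matching the bimodal marginal
  distribution of array M values; both groups share each feature's mean
  (no differential methylation);
* differentially variable (DV) features receive an independent group-2
  variance drawn with an inflated prior scale (1.5 by default, i.e. an
  average variance ratio of 1.5/0.64 = 2.34; 3.2 and 6.4 give five- and
  ten-fold ratios);
* outlier-bearing features have a single randomly chosen sample replaced
  by the global maximum M value of the pre-injection matrix — a
  one-point contamination that classical variance tests amplify.

All randomness flows from ``SimConfig.seed`` through NumPy
``SeedSequence`` spawning, so every table cell is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import bartlett_pvalues, f_test_pvalues
from .containers import DesignSpec, MethylMatrix, two_group_design
from .core import diffvar_pvalues
from .evaluate import fdr_power

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "draw_variances",
    "simulate_null",
    "simulate_dataset",
    "inject_outliers",
    "resample_split",
    "sample_size_sweep",
    "METHODS",
    "method_pvalues",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the benchmark conditions: 10,000 features, 50 samples
    per group, variance prior (d0=20, s0^2=0.64), bimodal means at +/-2
    with half the features methylated, and no DV or outlier features.
    """

    n_features: int = 10_000
    n_per_group: tuple[int, int] = (50, 50)
    d0: float = 20.0
    s0_sq: float = 0.64
    dv_s0_sq: float = 1.5
    n_dv: int = 0
    n_outliers: int = 0
    mean_low: float = -2.0
    mean_high: float = 2.0
    prop_methylated: float = 0.5
    allow_overlap: bool = False  # outlier features may coincide with DV features
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_dv < 0 or self.n_outliers < 0:
            raise ValueError("counts must be non-negative")
        if not self.allow_overlap and self.n_dv + self.n_outliers > self.n_features:
            raise ValueError("n_dv + n_outliers exceeds n_features")
        if self.d0 <= 0 or self.s0_sq <= 0 or self.dv_s0_sq <= 0:
            raise ValueError("prior parameters must be positive")


@dataclass
class SimTruth:
    """Ground-truth bookkeeping attached to a simulated matrix."""

    is_dv: np.ndarray  # True where group 2 is more variable by construction
    has_outlier: np.ndarray
    var_group1: np.ndarray
    var_group2: np.ndarray

    @property
    def is_null(self) -> np.ndarray:
        """Features with no true differential variability (outliers included)."""
        return ~self.is_dv

    def to_frame(self, probe_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "is_dv": self.is_dv,
                "has_outlier": self.has_outlier,
                "var_group1": self.var_group1,
                "var_group2": self.var_group2,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )


def draw_variances(
    count: int, d0: float, s0_sq: float, rng: np.random.Generator
) -> np.ndarray:
    """Scaled inverse chi-square draws: sigma^2 = d0 * s0^2 / chi2_{d0}.

    The theoretical mean is d0*s0^2/(d0-2) for d0 > 2; as d0 -> inf the
    draws concentrate at s0^2.
    """
    if d0 <= 0 or s0_sq <= 0:
        raise ValueError("d0 and s0_sq must be positive")
    return d0 * s0_sq / rng.chisquare(d0, size=count)


def _make_matrix(values: np.ndarray, n1: int, n2: int) -> tuple[MethylMatrix, DesignSpec]:
    g = values.shape[0]
    probe_ids = [f"cpg{i + 1}" for i in range(g)]
    sample_ids = [f"g1_s{j + 1}" for j in range(n1)] + [f"g2_s{j + 1}" for j in range(n2)]
    matrix = MethylMatrix(values=values, probe_ids=probe_ids, sample_ids=sample_ids, scale="M")
    design = two_group_design(n1, n2, sample_ids=sample_ids)
    return matrix, design


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[MethylMatrix, DesignSpec, SimTruth]:
    """Generate one dataset under the hierarchical model.

    Null features share one variance between groups; DV features draw
    group-1 and group-2 variances independently from the base and
    inflated priors; outliers are injected last, by default into
    non-DV features.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    g = config.n_features
    n1, n2 = config.n_per_group

    n_meth = int(round(g * config.prop_methylated))
    mu = np.full(g, config.mean_low)
    mu[rng.choice(g, size=n_meth, replace=False)] = config.mean_high

    var1 = draw_variances(g, config.d0, config.s0_sq, rng)
    var2 = var1.copy()
    is_dv = np.zeros(g, dtype=bool)
    if config.n_dv > 0:
        dv_idx = rng.choice(g, size=config.n_dv, replace=False)
        is_dv[dv_idx] = True
        # DV features: independent draws per group, group 2 inflated
        var1[dv_idx] = draw_variances(config.n_dv, config.d0, config.s0_sq, rng)
        var2[dv_idx] = draw_variances(config.n_dv, config.d0, config.dv_s0_sq, rng)

    values = rng.standard_normal((g, n1 + n2))
    values[:, :n1] *= np.sqrt(var1)[:, None]
    values[:, n1:] *= np.sqrt(var2)[:, None]
    values += mu[:, None]

    has_outlier = np.zeros(g, dtype=bool)
    if config.n_outliers > 0:
        eligible = np.arange(g) if config.allow_overlap else np.flatnonzero(~is_dv)
        values, has_outlier = _inject(values, config.n_outliers, rng, eligible)

    matrix, design = _make_matrix(values, n1, n2)
    truth = SimTruth(is_dv=is_dv, has_outlier=has_outlier, var_group1=var1, var_group2=var2)
    return matrix, design, truth


def simulate_null(config: SimConfig, rng: np.random.Generator | None = None):
    """Null dataset: no DV, no outliers (asserted on the config)."""
    if config.n_dv or config.n_outliers:
        raise ValueError("simulate_null requires n_dv = n_outliers = 0")
    return simulate_dataset(config, rng)


def _inject(
    values: np.ndarray, n_outliers: int, rng: np.random.Generator, eligible: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if n_outliers > eligible.size:
        raise ValueError("not enough eligible features for outlier injection")
    global_max = values.max()  # pre-injection maximum, first occurrence on ties
    rows = rng.choice(eligible, size=n_outliers, replace=False)
    cols = rng.integers(0, values.shape[1], size=n_outliers)
    out = values.copy()
    out[rows, cols] = global_max
    flags = np.zeros(values.shape[0], dtype=bool)
    flags[rows] = True
    return out, flags


def inject_outliers(
    matrix: MethylMatrix, n_outliers: int, rng: np.random.Generator
) -> tuple[MethylMatrix, np.ndarray]:
    """Replace one random sample in each of ``n_outliers`` random features
    with the global pre-injection maximum.  Returns the new matrix and
    the per-feature outlier flags."""
    values, flags = _inject(matrix.values, n_outliers, rng, np.arange(matrix.n_features))
    return (
        MethylMatrix(values=values, probe_ids=list(matrix.probe_ids),
                     sample_ids=list(matrix.sample_ids), scale=matrix.scale),
        flags,
    )


def resample_split(
    matrix: MethylMatrix,
    n_features: int,
    n1: int,
    n2: int,
    rng: np.random.Generator,
) -> tuple[MethylMatrix, DesignSpec]:
    """Subsample features and samples, splitting samples into two pseudo-groups.

    Feature rows keep their joint sample columns, preserving any
    correlation structure between features.  Sampling is without
    replacement; each selected sample lands in exactly one pseudo-group.
    """
    if n_features > matrix.n_features:
        raise ValueError("not enough features to resample")
    if n1 + n2 > matrix.n_samples:
        raise ValueError("not enough samples to split")
    feat = np.sort(rng.choice(matrix.n_features, size=n_features, replace=False))
    samp = rng.choice(matrix.n_samples, size=n1 + n2, replace=False)
    values = matrix.values[np.ix_(feat, samp)]
    probe_ids = [matrix.probe_ids[i] for i in feat]
    sample_ids = [matrix.sample_ids[j] for j in samp]
    sub = MethylMatrix(values=values, probe_ids=probe_ids, sample_ids=sample_ids, scale=matrix.scale)
    design = two_group_design(n1, n2, sample_ids=sample_ids)
    return sub, design


# --- method registry -------------------------------------------------------

def method_pvalues(name: str, values: np.ndarray, design: DesignSpec) -> np.ndarray:
    """Raw p-values for one registered test on an M-value array."""
    groups = np.asarray(design.groups)
    if name == "diffvar_abs":
        return diffvar_pvalues(values, design, method="abs")
    if name == "diffvar_sq":
        return diffvar_pvalues(values, design, method="sq")
    if name == "f_test":
        return f_test_pvalues(values, groups)[1]
    if name == "bartlett":
        return bartlett_pvalues(values, groups)[1]
    raise ValueError(f"unknown method {name!r}")


METHODS = ("diffvar_abs", "diffvar_sq", "f_test", "bartlett")


def _rep_rng(base_seed: int | None, *key: int) -> np.random.Generator:
    base = 0 if base_seed is None else int(base_seed)
    return np.random.default_rng(np.random.SeedSequence(base, spawn_key=tuple(int(k) for k in key)))


def sample_size_sweep(
    base_config: SimConfig,
    sizes: list[int],
    n_reps: int,
    methods: tuple[str, ...] = METHODS,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Observed FDR and power over a grid of per-group sample sizes.

    For each size and replicate, a fresh dataset is simulated under
    ``base_config`` with ``n_per_group = (size, size)``; each method's
    discoveries at the BH ``fdr`` cutoff are tallied against the truth.
    Replicate seeds derive deterministically from (base seed, size, rep).
    Returns a tidy frame with per-size means and Monte-Carlo standard
    errors of observed FDR and power (power is NaN when n_dv = 0).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    records = []
    for size in sizes:
        per_method: dict[str, list[tuple[float, float]]] = {m: [] for m in methods}
        for rep in range(n_reps):
            rng = _rep_rng(base_config.seed, size, rep)
            cfg = replace(base_config, n_per_group=(size, size))
            matrix, design, truth = simulate_dataset(cfg, rng)
            for m in methods:
                p = method_pvalues(m, matrix.values, design)
                obs_fdr, power, n_disc = fdr_power(p, truth.is_dv, fdr)
                per_method[m].append((obs_fdr, power))
        for m in methods:
            arr = np.asarray(per_method[m], dtype=float)
            records.append(
                {
                    "size": size,
                    "method": m,
                    "fdr": float(np.nanmean(arr[:, 0])),
                    "fdr_se": float(np.nanstd(arr[:, 0], ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.nan,
                    "power": float(np.nanmean(arr[:, 1])) if base_config.n_dv else np.nan,
                    "power_se": float(np.nanstd(arr[:, 1], ddof=1) / np.sqrt(n_reps)) if (n_reps > 1 and base_config.n_dv) else np.nan,
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame.from_records(records)
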