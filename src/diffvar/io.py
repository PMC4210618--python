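"""Readers and writers for matrices, sample sheets and result tables.

Matrices are delimiter-separated text (tab or comma, auto-detected from
the header with an override), features in rows with the first column
holding probe IDs, samples in columns.  Missing values are rejected, not
imputed: imputation would alter the per-feature variances that the tests
estimate.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DesignSpec, MethylMatrix

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "read_sample_sheet", "write_results", "read_results", "write_matrix"]


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(path: str | Path, scale: str = "M", sep: str | None = None) -> MethylMatrix:
    """Load a features x samples matrix; validates IDs, numerics and scale."""
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe IDs in {path.name}: {dups}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample IDs in {path.name}")
    try:
        values = df.astype(float)
    except ValueError:
        # locate the offending cell for a useful message
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric value at probe {row!r}, sample {col!r} in {path.name}"
                ) from None
        raise
    if values.isna().any().any():
        raise ValueError(f"missing values in {path.name}; filter probes before testing")
    return MethylMatrix(
        values=values.to_numpy(),
        probe_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        scale=scale,
    )


def write_matrix(matrix: MethylMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as delimited text at full float precision."""
    df = pd.DataFrame(matrix.values, index=matrix.probe_ids, columns=matrix.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_sample_sheet(
    path: str | Path,
    group_column: str = "group",
    sample_column: str = "sample_id",
    sep: str | None = None,
) -> DesignSpec:
    """Build a group-means design from a sample sheet.

    One indicator column per group (first-appearance order).  With
    exactly two groups the contrast is (-1, +1): group 2 minus group 1.
    With more groups a contrast must be supplied explicitly before
    testing; ``coef`` is left as None to force that choice.
    """
    path = Path(path)
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (sample_column, group_column):
        if col not in df.columns:
            raise ValueError(f"sample sheet {path.name} lacks column {col!r}")
    sample_ids = df[sample_column].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample IDs in sample sheet")
    groups = df[group_column].tolist()
    names = list(dict.fromkeys(groups))
    counts = {g: groups.count(g) for g in names}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    design = np.column_stack([[1.0 if g == name else 0.0 for g in groups] for name in names])
    if len(names) == 2:
        coef: int | np.ndarray = np.array([-1.0, 1.0])
    else:
        coef = None  # type: ignore[assignment]  # caller must choose a contrast
    return DesignSpec(design=design, coef=coef, groups=groups, group_names=names, sample_ids=sample_ids)


def write_results(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a result table, one row per feature, full float precision."""
    out = table.copy()
    if out.index.name is None:
        out.index.name = "probe_id"
    out.to_csv(path, sep=sep, float_format="%.17g")


def read_results(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0, float_precision="round_trip")
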