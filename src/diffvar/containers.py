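"""Core data containers: methylation matrices and design specifications.

A :class:`MethylMatrix` is a features x samples matrix of methylation
measurements on a declared scale — beta values (proportions in [0, 1]) or
M values (log2 methylated/unmethylated ratios).  A :class:`DesignSpec`
couples a full-rank design matrix with the coefficient or contrast under
test, optionally carrying the group labels it encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MethylMatrix", "DesignSpec", "two_group_design"]


@dataclass
class MethylMatrix:
    """A validated features x samples methylation matrix.

    Parameters
    ----------
    values
        2-D float array, one row per feature (e.g. CpG probe), one column
        per sample.
    probe_ids
        Unique feature identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    scale
        ``"M"`` for log2-ratio values or ``"beta"`` for proportions.
        Beta values must lie in [0, 1]; values at exactly 0 or 1 are only
        mapped away by an explicit clamp in the logit transform, never
        silently here.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    scale: str = "M"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D features x samples array")
        g, n = self.values.shape
        if g < 1 or n < 2:
            raise ValueError(f"need at least 1 feature and 2 samples, got {g}x{n}")
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.probe_ids) != g:
            raise ValueError("probe_ids length does not match number of rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of columns")
        if len(set(self.probe_ids)) != g:
            raise ValueError("duplicate probe IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")
        if self.scale == "beta":
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                bad = np.argwhere((self.values < 0) | (self.values > 1))[0]
                raise ValueError(
                    "beta values must lie in [0, 1]; offending entry at "
                    f"probe {self.probe_ids[bad[0]]}, sample {self.sample_ids[bad[1]]}"
                )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignSpec:
    """A design matrix plus the effect under test.

    ``design`` is the N x p model matrix (full column rank, N - p >= 1).
    ``coef`` selects the tested effect: either an integer column index or
    a length-p contrast vector.  ``groups`` optionally records the sample
    group labels when the design encodes a group-means model; each group
    must then contain at least two samples (variances are not estimable
    from singletons).
    """

    design: np.ndarray
    coef: int | np.ndarray = -1
    groups: list[str] | None = None
    group_names: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be a 2-D N x p matrix")
        n, p = self.design.shape
        if np.linalg.matrix_rank(self.design) < p:
            raise ValueError("design matrix is rank deficient")
        if n - p < 1:
            raise ValueError("need at least one residual degree of freedom (N - p >= 1)")
        if self.groups is not None:
            self.groups = [str(g) for g in self.groups]
            if len(self.groups) != n:
                raise ValueError("groups length does not match design rows")
            if self.group_names is None:
                # first-appearance order
                seen: list[str] = []
                for g in self.groups:
                    if g not in seen:
                        seen.append(g)
                self.group_names = seen
            for name in self.group_names:
                if self.groups.count(name) < 2:
                    raise ValueError(
                        f"group {name!r} has fewer than 2 samples; "
                        "variability is not estimable"
                    )

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_params(self) -> int:
        return self.design.shape[1]

    @property
    def df_residual(self) -> int:
        return self.design.shape[0] - self.design.shape[1]

    def contrast_vector(self) -> np.ndarray:
        """Return ``coef`` as an explicit length-p contrast vector."""
        p = self.n_params
        if self.coef is None:
            raise ValueError(
                "no contrast set: with more than two groups the tested "
                "contrast must be supplied explicitly"
            )
        if np.isscalar(self.coef) or isinstance(self.coef, (int, np.integer)):
            c = np.zeros(p)
            c[int(self.coef)] = 1.0
            return c
        c = np.asarray(self.coef, dtype=float)
        if c.shape != (p,):
            raise ValueError(f"contrast must have length p={p}")
        return c

    def group_masks(self) -> dict[str, np.ndarray]:
        """Boolean sample mask per group, keyed by group name, in order."""
        if self.groups is None:
            raise ValueError("design does not carry group labels")
        labels = np.asarray(self.groups)
        return {name: labels == name for name in self.group_names}

    def aligned_to(self, sample_ids: list[str]) -> "DesignSpec":
        """Reorder rows to match ``sample_ids`` exactly.

        Alignment is explicit: missing or extra samples raise with the
        offending identifiers listed; the design is never silently
        reordered by consumers.
        """
        if self.sample_ids is None:
            raise ValueError("DesignSpec has no sample_ids to align on")
        mine, target = set(self.sample_ids), set(sample_ids)
        if mine != target:
            missing = sorted(target - mine)
            extra = sorted(mine - target)
            raise ValueError(
                f"sample mismatch: missing from design {missing}; not in matrix {extra}"
            )
        order = [self.sample_ids.index(s) for s in sample_ids]
        return DesignSpec(
            design=self.design[order],
            coef=self.coef,
            groups=[self.groups[i] for i in order] if self.groups is not None else None,
            group_names=self.group_names,
            sample_ids=list(sample_ids),
        )


def two_group_design(
    n1: int,
    n2: int,
    names: tuple[str, str] = ("group1", "group2"),
    sample_ids: list[str] | None = None,
) -> DesignSpec:
    """Group-means design for two groups with the difference contrast.

    Columns are group indicators; the contrast (-1, +1) tests
    mean(group2) - mean(group1).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    design = np.zeros((n1 + n2, 2))
    design[:n1, 0] = 1.0
    design[n1:, 1] = 1.0
    groups = [names[0]] * n1 + [names[1]] * n2
    return DesignSpec(
        design=design,
        coef=np.array([-1.0, 1.0]),
        groups=groups,
        group_names=list(names),
        sample_ids=sample_ids,
    )
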