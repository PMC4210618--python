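"""Scale conversions: intensities, beta values and M values.

M values are log2 ratios of methylated to unmethylated intensity, with a
small positive offset added to both channels to stabilise low-intensity
probes (platform convention: 100).  Beta values are methylated over total
intensity, a proportion in [0, 1].  The two scales interconvert through a
base-2 logit: M = log2(beta / (1 - beta)), beta = 2^M / (2^M + 1).  The
base-2 logit is used (rather than natural log) so that the beta<->M map
agrees with the intensity-ratio definition of M when offsets vanish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import MethylMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityPair",
    "intensities_to_m",
    "intensities_to_beta",
    "beta_to_m",
    "m_to_beta",
]

DEFAULT_OFFSET = 100.0
DEFAULT_CLAMP_EPS = 1e-6


@dataclass
class IntensityPair:
    """Paired methylated / unmethylated signal intensities."""

    methylated: np.ndarray
    unmethylated: np.ndarray
    offset: float = DEFAULT_OFFSET
    probe_ids: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.methylated = np.atleast_2d(np.asarray(self.methylated, dtype=float))
        self.unmethylated = np.atleast_2d(np.asarray(self.unmethylated, dtype=float))
        if self.methylated.shape != self.unmethylated.shape:
            raise ValueError("methylated and unmethylated matrices must be conformable")
        if np.any(self.methylated < 0) or np.any(self.unmethylated < 0):
            raise ValueError("intensities must be non-negative")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if self.offset == 0 and (
            np.any(self.methylated == 0) or np.any(self.unmethylated == 0)
        ):
            raise ValueError("offset must be positive when any intensity is zero")

    def _ids(self) -> tuple[list[str], list[str]]:
        g, n = self.methylated.shape
        probes = self.probe_ids or [f"probe{i + 1}" for i in range(g)]
        samples = self.sample_ids or [f"sample{j + 1}" for j in range(n)]
        return probes, samples


def intensities_to_m(pair: IntensityPair) -> MethylMatrix:
    """M = log2((meth + offset) / (unmeth + offset))."""
    m = np.log2((pair.methylated + pair.offset) / (pair.unmethylated + pair.offset))
    probes, samples = pair._ids()
    return MethylMatrix(values=m, probe_ids=probes, sample_ids=samples, scale="M")


def intensities_to_beta(pair: IntensityPair) -> MethylMatrix:
    """beta = meth / (meth + unmeth + offset).

    The offset enters the denominator only (platform convention); set
    ``offset=0`` for the plain proportion.
    """
    denom = pair.methylated + pair.unmethylated + pair.offset
    if np.any(denom == 0):
        raise ValueError("zero total intensity with zero offset")
    beta = pair.methylated / denom
    probes, samples = pair._ids()
    return MethylMatrix(values=beta, probe_ids=probes, sample_ids=samples, scale="beta")


def beta_to_m(matrix: MethylMatrix, clamp_eps: float = DEFAULT_CLAMP_EPS) -> MethylMatrix:
    """Base-2 logit: M = log2(beta / (1 - beta)).

    Beta values at exactly 0 or 1 would map to infinite M; they are
    clamped into [clamp_eps, 1 - clamp_eps] with a logged warning — an
    explicit, documented clamp rather than a silent infinity.
    """
    if matrix.scale != "beta":
        raise ValueError("beta_to_m expects a beta-scale matrix")
    beta = matrix.values
    n_clamped = int(np.sum((beta <= 0) | (beta >= 1)))
    if n_clamped:
        logger.warning("beta_to_m: clamping %d boundary beta values to eps=%g", n_clamped, clamp_eps)
        beta = np.clip(beta, clamp_eps, 1.0 - clamp_eps)
    m = np.log2(beta / (1.0 - beta))
    return MethylMatrix(values=m, probe_ids=list(matrix.probe_ids), sample_ids=list(matrix.sample_ids), scale="M")


def m_to_beta(matrix: MethylMatrix) -> MethylMatrix:
    """Inverse base-2 logit: beta = 2^M / (2^M + 1)."""
    if matrix.scale != "M":
        raise ValueError("m_to_beta expects an M-scale matrix")
    m = matrix.values
    # exp-safe form: for large |M| use the symmetric sigmoid identity
    beta = np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)), np.exp2(m) / (np.exp2(np.minimum(m, 0)) + 1.0))
    return MethylMatrix(values=beta, probe_ids=list(matrix.probe_ids), sample_ids=list(matrix.sample_ids), scale="beta")
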