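import numpy as np
import pytest

from diffvar import MethylMatrix, SimConfig, simulate_dataset, two_group_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_m_matrix(rng):
    """A 30-feature, 6+6-sample M-value matrix with mild group structure."""
    values = rng.standard_normal((30, 12)) + np.tile([-2, 2], 15)[:, None]
    return MethylMatrix(
        values=values,
        probe_ids=[f"cg{i:05d}" for i in range(30)],
        sample_ids=[f"s{j}" for j in range(12)],
        scale="M",
    )


@pytest.fixture
def small_design(small_m_matrix):
    return two_group_design(6, 6, sample_ids=small_m_matrix.sample_ids)


@pytest.fixture
def null_dataset():
    """One mid-sized null dataset under the hierarchical model."""
    rng = np.random.default_rng(777)
    return simulate_dataset(SimConfig(n_features=2000, n_per_group=(20, 20)), rng)
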