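import numpy as np
import pytest

from hierfc import CohortSpec, SubNetworkPartition, WindowSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_partition():
    """Three sub-networks over 11 ROIs, one named DMN for effect injection."""
    return SubNetworkPartition(networks={"A": [0, 1, 2, 3], "B": [4, 5, 6],
                                         "DMN": [7, 8, 9, 10]})


@pytest.fixture
def small_cohort(small_partition):
    """12 + 12 subjects, 80 time points, moderate group effect in DMN."""
    spec = CohortSpec(n_asd=12, n_nc=12, m_time=80, partition=small_partition,
                      state_dwell=20, effect_delta=-0.3, noise_sd=0.4, seed=7)
    subjects, labels, truth = generate_cohort(spec)
    return spec, subjects, labels, truth


@pytest.fixture
def window30():
    return WindowSpec(width=30, step=10)
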