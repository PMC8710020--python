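import numpy as np
import pytest

from mihcquant import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-patient cohort shared by read-only tests."""
    cfg = SimConfig(n_patients=6, cells_per_core_mean=400, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
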