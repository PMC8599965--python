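import numpy as np
import pytest

from pspdyn import synth


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort shared by read-only tests."""
    spec = synth.CohortSpec(
        n_control=10, n_case=10, n_channels=10, n_timepoints=200, n_states=4, seed=42
    )
    return synth.simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
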