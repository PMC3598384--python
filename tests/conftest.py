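import numpy as np
import pytest

from resiliometry import synthetic as syn


@pytest.fixture(scope="session")
def calibrated_cohort_10k():
    """One large cohort under the default calibration, shared across tests."""
    cfg = syn.default_config(n_children=10_000, seed=101)
    return syn.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for pipeline-level tests."""
    cfg = syn.default_config(n_children=600, seed=42)
    return syn.generate_cohort(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
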