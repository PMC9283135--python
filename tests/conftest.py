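import numpy as np
import pytest

from moca_psci import SimulationConfig, run_study, simulate_study
from moca_psci.adjudication import TestResult

TestResult.__test__ = False  # domain type, not a test class


@pytest.fixture(scope="session")
def default_study():
    """One seeded default-size synthetic study shared across tests."""
    config = SimulationConfig(seed=20240901)
    records, assessments, truth = simulate_study(config)
    return config, records, assessments, truth


@pytest.fixture(scope="session")
def default_report(default_study):
    _, records, assessments, _ = default_study
    return run_study(records, assessments)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
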