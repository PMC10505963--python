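import numpy as np
import pytest

import psmcea
from psmcea import PartitionedSurvivalCEA, base_case_config


@pytest.fixture()
def base_config():
    """Fresh base-case config (mutable; function-scoped)."""
    return base_case_config()


@pytest.fixture(scope="session")
def base_results():
    """Base-case fit, shared read-only across tests."""
    return PartitionedSurvivalCEA().fit()


@pytest.fixture(scope="session")
def loglogistic_cohort():
    """A simulated log-logistic cohort with realistic trial censoring."""
    spec = psmcea.SimulationSpec(
        psmcea.ParametricSurvival("loglogistic", (2.0, 0.03)),
        n=500, admin_cutoff_weeks=150.0, random_censor_rate=0.003, seed=5)
    return spec, psmcea.simulate_ipd(spec)
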