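import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from numstroop.design import DesignConfig, build_design
from numstroop.simulate import default_truth, generate_covariates, generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """One small synthetic study reused across tests (8 participants)."""
    cfg = DesignConfig(n_participants=8, seed=7)
    schedule = build_design(cfg)
    trials = generate_dataset(schedule, default_truth(), seed=11, dt=1e-3)
    return cfg, schedule, trials


@pytest.fixture(scope="session")
def tms_trials(study):
    _, _, trials = study
    return trials[trials["session"] == "tms"]


@pytest.fixture(scope="session")
def covariates():
    return generate_covariates(8, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
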