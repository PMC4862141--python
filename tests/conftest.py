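import numpy as np
import pytest

from pdxtrial import StudyDesign, synth_trial


@pytest.fixture
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def default_trial():
    """One simulated nine-arm study shared by read-only tests."""
    return synth_trial.simulate_trial(synth_trial.default_sim_config(seed=20240901))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
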