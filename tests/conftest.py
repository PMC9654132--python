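import numpy as np
import pytest

import satkit as sk


@pytest.fixture(scope="session")
def default_params() -> sk.TraineeParams:
    return sk.TraineeParams()


@pytest.fixture(scope="session")
def adaptive_record(default_params) -> sk.SessionRecord:
    """One full-protocol closed-loop participant, shared across tests."""
    return sk.simulate_participant(
        default_params, sk.default_policy_for("stress_adaptive"), seed=2024
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
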