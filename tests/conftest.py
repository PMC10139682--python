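import numpy as np
import pytest

from lcstrial.simulate import SimConfig, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """One mid-sized synthetic trial with instrument-wise wave-2 MCAR."""
    return generate_trial(
        SimConfig(
            seed=20260920,
            n_intervention=600,
            n_control=600,
            missingness={"mode": "mcar_by_instrument"},
        )
    )


@pytest.fixture(scope="session")
def complete_trial():
    """A complete-data synthetic trial (no missingness)."""
    return generate_trial(
        SimConfig(
            seed=11,
            n_intervention=500,
            n_control=500,
            missingness={"mode": "none"},
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
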