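import numpy as np
import pytest

from capstate.config import Group, SimulationConfig
from capstate.synthetic import make_state_templates, simulate_cohort, simulate_subject


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    """Desk-scale default conditions (7 states, 32x16 grid)."""
    return SimulationConfig(seed=12345)


@pytest.fixture(scope="session")
def templates(desk_config):
    return make_state_templates(desk_config)


@pytest.fixture(scope="session")
def wt_recording(desk_config, templates):
    return simulate_subject(templates, desk_config, Group.WT, seed=42, subject_id="WT-fix")


@pytest.fixture(scope="session")
def clean_two_state_cohort():
    """Noise-free 2-state recordings: frames exactly equal their templates."""
    config = SimulationConfig(
        seed=7, n_states=2, noise_sd=0.0, n_wt=2, n_tg=2, n_frames_per_subject=120
    )
    return config, simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
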