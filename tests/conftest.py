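import numpy as np
import pytest
from hypothesis import settings

from dynbias.glm import GLMParams
from dynbias.task import TaskConfig, simulate_trials

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def test_phase_trials():
    """A moderate test-phase-like sequence shared across fitting tests."""
    return simulate_trials(TaskConfig.test_phase(4000, seed=11))


def glm_observers():
    """Three model observers sharing task weights but differing in history
    reliance and in the evolution of their aligned bias (rising / flat /
    slowly falling)."""
    shared = dict(w_alpha=0.0, w_theta=0.35, w_e=0.35, w_C=-0.25)
    return [
        GLMParams(**shared, w_S=-0.8, w_r=0.3, w_p=0.02, gamma=0.5),
        GLMParams(**shared, w_S=0.0, w_r=0.1, w_p=-0.05, gamma=1.0),
        GLMParams(**shared, w_S=0.6, w_r=0.5, w_p=0.05, gamma=0.15),
    ]
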