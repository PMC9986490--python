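import numpy as np
import pytest

from aifintercept import EnvConfig, EpisodeSetup


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def env_config():
    return EnvConfig()


@pytest.fixture
def no_change_setup():
    """Episode whose target never changes speed (final == initial)."""
    return EpisodeSetup(agent_init_distance=27.0, target_init_speed=11.25,
                        target_final_speed=11.25, change_onset=2.5,
                        ramp_duration=0.5, target_init_distance=45.0)
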