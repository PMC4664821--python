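import numpy as np
import pytest

from rtg.synth import SynthConfig, draw_subject_effects


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zero_noise_config():
    return SynthConfig().with_zero_noise()


@pytest.fixture
def default_config():
    return SynthConfig()


@pytest.fixture
def subject(zero_noise_config):
    # zero-noise subject effects are deterministic (all dispersions zero)
    return draw_subject_effects(zero_noise_config, np.random.default_rng(0))[0]
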