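import numpy as np
import pytest

from whiskeye.synthetic_data import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless mid-sized session with coupling enabled."""
    cfg = GeneratorConfig(
        n_trials=12, seed=11, noise_sd_whisker=0.0, noise_sd_eye=0.0, saccade_rate=0.6
    )
    session, truth = generate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise session used by integration-style tests."""
    cfg = GeneratorConfig(n_trials=10, seed=23)
    session, truth = generate_session(cfg)
    return cfg, session, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
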