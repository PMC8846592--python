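import numpy as np
import pytest
from hypothesis import settings

import laminfo as L

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """Small but analyzable synthetic session (fast to generate)."""
    return L.SynthConfig(n_trials_per_condition=40, seed=7)


@pytest.fixture(scope="session")
def small_session(small_config):
    return L.generate_session(small_config)


@pytest.fixture(scope="session")
def default_session():
    """One session at the study-condition defaults."""
    cfg = L.SynthConfig(seed=11)
    return cfg, L.generate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
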