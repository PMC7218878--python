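import numpy as np
import pytest

from pttbp.models import ModelParams
from pttbp.synth import ProtocolConfig, simulate_subject


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    """The reference parameter set used by the worked examples."""
    return ModelParams.from_cuff_pair(sbp0=120.0, dbp0=80.0, ptt0=250.0, gamma=0.017)


@pytest.fixture(scope="session")
def noiseless_subject():
    """A fully deterministic subject: no PTT noise, no cuff noise."""
    cfg = ProtocolConfig(seed=11, ptt_noise_sd=0.0, cuff_noise_sd=0.0)
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def noisy_subject():
    """A subject at the generator's default noise levels."""
    return simulate_subject(ProtocolConfig(seed=23))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
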