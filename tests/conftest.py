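import numpy as np
import pytest

from hypnoseeg import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One 60 s default-condition simulation shared across tests."""
    cfg = SyntheticConfig(duration=60.0, seed=42)
    rec, events, sources, mixing = simulate(cfg)
    return cfg, rec, events, sources, mixing


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
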