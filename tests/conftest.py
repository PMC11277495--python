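import numpy as np
import pytest

from flysleep import LightProtocol, SimConfig, simulate_group


@pytest.fixture
def protocol():
    return LightProtocol()  # 2 LD + 8 DD days, 30-s bins


@pytest.fixture
def short_protocol():
    """2 LD + 2 DD days: enough for every code path, fast to simulate."""
    return LightProtocol(ld_days=2, dd_days=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240707)


@pytest.fixture(scope="session")
def small_cohort():
    """8 wildtype-like flies over the full 10-day protocol (session cache)."""
    cfg = SimConfig(n_flies=8, seed=11)
    recs, truths, manifest = simulate_group(cfg)
    return recs, truths, manifest
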