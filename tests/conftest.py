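import numpy as np
import pandas as pd
import pytest

from herdscope import sim


@pytest.fixture(scope="session")
def small_sim():
    """One simulated day of a small untethered herd, no battery death."""
    cfg = sim.SimulationConfig(n_individuals=6, n_juveniles=2, duration_days=1,
                               rng_seed=42)
    return sim.simulate_herd(cfg)


@pytest.fixture(scope="session")
def tether_sim():
    """One simulated day of a small herd with juveniles tethered at night."""
    cfg = sim.SimulationConfig(
        n_individuals=6, n_juveniles=2, duration_days=1, rng_seed=42,
        tether_enabled=True, tether_positions=tuple(sim.default_tether_line(2)))
    return sim.simulate_herd(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def utc(s: str) -> pd.Timestamp:
    return pd.Timestamp(s, tz="UTC")
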