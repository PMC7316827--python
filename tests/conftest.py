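"""Shared fixtures: simulated records reused across test modules."""

import numpy as np
import pytest

from fecgkit import simulate as sim


@pytest.fixture(scope="session")
def short_record():
    """2-minute record at the mean antenatal operating point."""
    cfg = sim.SimulationConfig(duration_s=120.0, seed=11)
    return sim.generate_record(cfg)


@pytest.fixture(scope="session")
def noiseless_record():
    """2-minute record with all noise and timing jitter switched off."""
    cfg = sim.noiseless(sim.SimulationConfig(duration_s=120.0, seed=11))
    return sim.generate_record(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
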