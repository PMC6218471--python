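import numpy as np
import pytest

import circuitnoise as cn


@pytest.fixture(scope="session")
def ts():
    return cn.fixture_circuit("TS")


@pytest.fixture(scope="session")
def ts_sa1():
    return cn.fixture_circuit("TS_SA1")


@pytest.fixture(scope="session")
def ts_sa2():
    return cn.fixture_circuit("TS_SA2")


@pytest.fixture(scope="session")
def default_ranges():
    return cn.ParameterRanges()


@pytest.fixture(scope="session")
def toggle_model(ts, default_ranges):
    """One reproducible random toggle-switch model."""
    return cn.sample_model(ts, default_ranges, np.random.default_rng(7))


@pytest.fixture(scope="session")
def quadrastable_10k(ts_sa2):
    """Deterministic state enumeration of 10,000 random self-activating
    toggle-switch models under the quadrastable calibration; shared by the
    multistability, annealing and induction tests (it is the expensive
    step of all three)."""
    return cn.find_quadrastable(
        ts_sa2, cn.QUADRASTABLE_RANGES, 10_000, seed=2024, t_max=250.0
    )
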