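import numpy as np
import pytest

from mtswitch.kmc_engine import (
    ConcentrationProtocol,
    KineticParams,
    SimConfig,
    Trace,
    simulate_trace,
)


@pytest.fixture(scope="session")
def default_params():
    return KineticParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250920)


def make_trace(times, lengths_nm, sample_dt=None, censored=False):
    """Hand-built trace with minimal metadata, for analysis-layer tests."""
    return Trace(
        times=np.asarray(times, dtype=float),
        lengths_nm=np.asarray(lengths_nm, dtype=float),
        metadata={"params": {}, "protocol": {}, "sim": {}, "seed": 0},
        censored=censored,
    )


@pytest.fixture(scope="session")
def growth_trace(default_params):
    """One short growing filament at high concentration (warm JIT too)."""
    return simulate_trace(
        default_params,
        ConcentrationProtocol(C0=14.0),
        SimConfig(duration=120.0, seed=7),
    )
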