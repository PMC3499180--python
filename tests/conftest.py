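import pytest

from growthplate.parameters import TABULATED_LOAD_CASES
from growthplate.simulation import SimulationConfig, run


@pytest.fixture(scope="session")
def full_runs():
    """23-day simulations of all four tabulated load cases (shared)."""
    return {
        ds: run(SimulationConfig(delta_sigma_n=ds, duration=23.0))
        for ds in TABULATED_LOAD_CASES
    }
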