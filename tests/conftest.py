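import numpy as np
import pytest

from gpfcs import SimulationConfig, mean_molecules_for_occupancy, simulate_trace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_config(n_spot=10.0, omega0=290.0, **kw):
    """Standard acquisition config: spot occupancy given, box = 10 omega0."""
    box = 10.0 * omega0 * 1e-3
    defaults = dict(
        box_side=box,
        omega0=omega0,
        mean_molecules=mean_molecules_for_occupancy(n_spot, box, omega0),
        d_true=5.0,
        brightness=25.0,
        bin_width=1e-6,
        duration=10.0,
        seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def short_trace():
    """A quick 1-s free-diffusion trace shared by correlation/fit tests."""
    cfg = make_config(duration=1.0, bin_width=5e-6, d_true=2.0, seed=7)
    return simulate_trace(cfg)
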