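import numpy as np
import pytest

from stemwave import experiments
from stemwave.crowding import CROWDING_FUNCTIONS

ALL_F = sorted(CROWDING_FUNCTIONS)

#: printed benchmark values: death rate -> (numerical, theoretical)
BENCHMARK_SPEEDS = {
    5.0: (2.0340, 2.0000),
    1.0: (2.0044, 2.0000),
    0.8: (1.7757, 1.7889),
    0.5: (1.4036, 1.4142),
    0.05: (0.4111, 0.4472),
}


@pytest.fixture(scope="session")
def benchmark_speeds():
    """Measured slow-system speeds at the benchmark settings (d=1,
    step IC at x=20, tau in [0,80], dx=0.1), shared across tests."""
    return {alpha: experiments.slow_front_speed(alpha).speed
            for alpha in BENCHMARK_SPEEDS}


@pytest.fixture(scope="session")
def abm_sweep():
    """Replicate lattice front speeds across the death-rate sweep
    (full 500x50 lattice, 7000 MCS, 5 seeds); shared across tests."""
    return experiments.abm_speed_sweep(
        alphas=(0.0, 0.05, 0.1, 0.15, 0.25, 0.35),
        seeds=(1, 2, 3, 4, 5), n_mcs=7000,
    )
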