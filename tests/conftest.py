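import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from hnokinetics import (
    DEFAULT_CONDITIONS,
    DEFAULT_OPTICS,
    DEFAULT_RATES,
    default_concentration_grid,
    generate_series,
    integrate_full_model,
)


@pytest.fixture(scope="session")
def noiseless_optics():
    return DEFAULT_OPTICS.noiseless()


@pytest.fixture(scope="session")
def control_trajectory():
    """Reference-condition trajectory, no scavenger, 600 s at 1 s sampling."""
    return integrate_full_model(DEFAULT_RATES, DEFAULT_CONDITIONS)


@pytest.fixture(scope="session")
def noiseless_series_2200(noiseless_optics):
    """Noiseless competition series for k_true = 2.2e3 M^-1 s^-1."""
    return generate_series(
        2.2e3,
        default_concentration_grid(2.2e3),
        replicates=3,
        optics=noiseless_optics,
        seed=7,
    )
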