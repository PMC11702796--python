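import numpy as np
import pytest

from stabscan.rex import wham_solve
from stabscan.synthetic import (SpectraSimConfig, ZimmBraggConfig,
                                simulate_rex_zimm_bragg,
                                simulate_spectra_series)


@pytest.fixture(scope="session")
def zb_config():
    """Reference helix-coil system: independent sites, melting near 330 K."""
    return ZimmBraggConfig(seed=11)


@pytest.fixture(scope="session")
def zb_dataset(zb_config):
    """One full replica-exchange run of the reference system (20k frames)."""
    return simulate_rex_zimm_bragg(zb_config)


@pytest.fixture(scope="session")
def zb_wham(zb_dataset):
    return wham_solve(zb_dataset)


@pytest.fixture
def noise_free_thermal_series():
    cfg = SpectraSimConfig(mode="thermal", noise_sigma=0.0, seed=0)
    return cfg, simulate_spectra_series(cfg)


@pytest.fixture
def noise_free_chemical_series():
    cfg = SpectraSimConfig(mode="chemical", noise_sigma=0.0, seed=0,
                           conditions=np.arange(0.0, 4.01, 0.25))
    return cfg, simulate_spectra_series(cfg)
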