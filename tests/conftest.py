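import numpy as np
import pytest

import dustflux as dfx


@pytest.fixture(scope="session")
def small_grid():
    """Compact 10x10-degree ocean box with 1 km bins to 7 km."""
    return dfx.GridDef(lat_min=10, lat_max=20, lon_min=50, lon_max=60, cell_deg=2)


@pytest.fixture(scope="session")
def clean_granule():
    """Noise-free two-component granule with one elevated dust layer."""
    spec = dfx.GranuleSpec(
        n_profiles=50,
        lat_range=(12, 18),
        lon_range=(52, 58),
        dust_layers=((500.0, 3500.0, 0.1),),
        nondust_background=0.01,
        seed=11,
    )
    return dfx.make_granule(spec)


@pytest.fixture(scope="session")
def gaussian_scenario():
    grid = dfx.GridDef(cell_deg=2)
    return dfx.make_plume("gaussian_plume", grid=grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
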