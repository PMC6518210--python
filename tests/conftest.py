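import numpy as np
import pytest

import opfgrid as og


@pytest.fixture(scope="session")
def ie1_field():
    return og.ie1_preset()


@pytest.fixture(scope="session")
def ie2_field():
    return og.ie2_preset()


@pytest.fixture(scope="session")
def stations225(ie1_field):
    """Noiseless 225-station twin-experiment network."""
    return og.sample_stations(ie1_field, n=225, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_domain():
    return og.DomainBox(0.0, 1.0, 0.0, 1.0)


def random_stations(rng, n, domain, values=None):
    """Well-spread random stations on a domain (helper, not a fixture)."""
    lons = domain.lon_min + rng.random(n) * domain.width
    lats = domain.lat_min + rng.random(n) * domain.height
    if values is None:
        values = rng.normal(50.0, 10.0, size=n)
    ids = [f"T{i}" for i in range(n)]
    return og.StationSet(ids=ids, lons=lons, lats=lats, values=values)
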