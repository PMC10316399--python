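import numpy as np
import pytest

from gslnano import DomainModel, FretParameters, place_domains


@pytest.fixture(scope="session")
def params():
    """Photophysics of the synthetic Bodipy-like donor/acceptor pair."""
    return FretParameters(forster_radius_nm=5.7, donor_lifetime_ns=5.7, r_min_nm=1.0)


@pytest.fixture(scope="session")
def domain_config():
    """A mid-coverage disc configuration reused across tests."""
    model = DomainModel(
        radius_nm=10.0, area_fraction=0.3, box_length_nm=200.0,
        partition_donor=5.0, partition_acceptor=5.0,
    )
    return place_domains(model, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
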