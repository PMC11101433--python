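import numpy as np
import pytest

import fossildiv as fd


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def desk_config():
    return fd.SimulationConfig.desk_scale()


@pytest.fixture(scope="session")
def small_corpus(desk_config):
    """A dozen full desk-scale datasets shared across test modules."""
    return fd.generate_corpus(desk_config, 12, seed=777, with_features=True)


@pytest.fixture(scope="session")
def toy_record():
    """Hand-enumerated record: 3 species, 2 regions, 2 bins.

    occurrences (species, region, bin, locality):
      (0, 0, 0, 0), (0, 1, 0, 0), (1, 0, 0, 0), (1, 0, 1, 1), (2, 1, 1, 0)
    """
    from fossildiv.fossil import FossilRecord, LocalityGrid

    l_at = np.array([[1, 2], [1, 1]])
    return FossilRecord(
        species=np.array([0, 0, 1, 1, 2]),
        region=np.array([0, 1, 0, 0, 1]),
        bin=np.array([0, 0, 0, 1, 1]),
        locality=np.array([0, 0, 0, 1, 0]),
        grid=LocalityGrid(lambda_at=l_at.astype(float), l_at=l_at),
        n_species=3,
        n_regions=2,
        n_bins=2,
    )
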