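import numpy as np
import pytest

from lichenmonitor import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spectra():
    """A 60-sample labelled spectra matrix on the full grid (fixed seed)."""
    return synthetic.generate_spectra(synthetic.SpectraSimConfig(n_samples=60, seed=3))


@pytest.fixture(scope="session")
def small_survey():
    """Two-campaign survey over 2 stations x 3 trees, 10 species (fixed seed)."""
    pool = synthetic.default_species_pool(10, eutrophication_effect=-0.4, seed=1)
    cfg = synthetic.CommunitySimConfig(
        species_pool=pool, n_stations=2, trees_per_station=3, seed=1
    )
    return synthetic.generate_survey(cfg)
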