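import numpy as np
import pytest

from nichescape.core import CommunityMatrix, Landscape
from nichescape.synthetic_data import gen_community, gen_cube, gen_landscape, make_species_spectra


@pytest.fixture(scope="session")
def small_landscape() -> Landscape:
    return gen_landscape(width=12, height=12, n_types=3, autocorr_range=5.0, seed=101)


@pytest.fixture(scope="session")
def niche_truth(small_landscape):
    """Community with moderate niche filtering and dispersal clustering."""
    return gen_community(
        small_landscape, n_species=10, niche_strength=2.0, aggregation=1.0, seed=202, pixels_per_cell=5
    )


@pytest.fixture(scope="session")
def clean_cube(niche_truth):
    """Low-noise cube over well-separated species, no planted invalid pixels."""
    wl, spectra = make_species_spectra(niche_truth.n_species, n_bands=60, seed=303, separation=0.1)
    cube, planted = gen_cube(niche_truth, spectra, wl, noise_sd=0.004, invalid_fraction=0.0, seed=404)
    return cube


@pytest.fixture
def random_community():
    rng = np.random.default_rng(7)
    n = 20
    return CommunityMatrix(
        site_ids=np.arange(n),
        coords=rng.uniform(0, 1000, (n, 2)),
        counts=rng.integers(0, 30, (n, 8)) + 1,
        species_ids=np.arange(8),
    )
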