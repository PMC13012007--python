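import pytest

from grscreen import compute_growth_table, generate_idealized_samples, generate_library
from grscreen.dose_response import fit_library


@pytest.fixture(scope="session")
def idealized_areas():
    return generate_idealized_samples()


@pytest.fixture(scope="session")
def idealized_growth(idealized_areas):
    return compute_growth_table(idealized_areas)


@pytest.fixture(scope="session")
def noiseless_library():
    """Small noise-free library with known ground-truth parameters."""
    table, specs = generate_library(6, seed=11, noise_sd=0.0)
    return table, specs


@pytest.fixture(scope="session")
def noiseless_fits(noiseless_library):
    table, specs = noiseless_library
    growth = compute_growth_table(table)
    return fit_library(growth, "gr"), fit_library(growth, "area"), specs
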