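import pytest

from dognorm import GridSpec, ModelUnit, canonical_units, population_sweep


@pytest.fixture(scope="session")
def unit22():
    """The worked-example encoder: surround 2x, normalization 2x the center."""
    return ModelUnit(sigma_s=2.0, sigma_n=2.0)


@pytest.fixture(scope="session")
def family():
    return canonical_units()


@pytest.fixture(scope="session")
def coarse_grid():
    """Low-resolution lattice for exactness properties (resolution-independent)."""
    return GridSpec(pixels_per_sigma_c=8, half_width=10.0)


@pytest.fixture(scope="session")
def population_table():
    """Canonical 42-unit sweep at the default resolution (16 px per sigma_c)."""
    return population_sweep()
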