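import numpy as np
import pytest

from coverwise.scene import (make_spectral_library, make_wavelength_grid,
                             render_cube, simulate_cover_field)


@pytest.fixture(scope="session")
def wl_small():
    return make_wavelength_grid(48)


@pytest.fixture(scope="session")
def library_small(wl_small):
    return make_spectral_library(wl_small, n_background=5, seed=7,
                                 separability=0.03)


@pytest.fixture(scope="session")
def scene_small():
    return simulate_cover_field(rows=160, cols=160, correlation_length_m=5.0,
                                prevalence_target=0.045, seed=3)


@pytest.fixture(scope="session")
def cube_small(scene_small, library_small):
    return render_cube(scene_small, library_small, noise_sd=0.01, seed=11)


@pytest.fixture(scope="session")
def design_small(scene_small):
    from coverwise.sampling import place_reference_polygons

    return place_reference_polygons(scene_small, n_target=24,
                                    strata_counts=(6, 6, 12), n_background=40,
                                    min_spacing_m=5.0, seed=5)


@pytest.fixture
def rng():
    # function-scoped so every test sees the same fresh stream
    return np.random.default_rng(2024)
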