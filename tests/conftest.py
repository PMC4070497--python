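import numpy as np
import pytest

from afspect import (
    ComponentLibrary,
    GRID_PRESETS,
    SpectralComponent,
    default_library,
    make_mixture,
)

#: a typical control-liver composition (area shares, %)
CONTROL_WEIGHTS = {
    "nadph_free": 30.0, "nadph_bound": 20.0, "flavins": 12.0,
    "vitamin_a": 6.0, "fatty_acids": 12.0, "proteins": 15.0,
    "lipopigments": 5.0,
}


@pytest.fixture(scope="session")
def in_vivo_grid():
    return GRID_PRESETS["in_vivo"]


@pytest.fixture(scope="session")
def ex_vivo_grid():
    return GRID_PRESETS["ex_vivo"]


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def fixed_shape_library(library):
    """Default library with every shape frozen (amplitude-only fitting)."""
    return ComponentLibrary([
        c.with_params(center_free=False, fwhm_free=False, asymmetry_free=False,
                      bounds={})
        for c in library
    ])


@pytest.fixture()
def control_mixture(in_vivo_grid):
    spec, truth = make_mixture(CONTROL_WEIGHTS, in_vivo_grid, seed=42)
    return spec, truth


def gaussian(wl, center, fwhm, amplitude=1.0):
    """Analytic reference Gaussian used as the symmetric-limit oracle."""
    return amplitude * np.exp(-4 * np.log(2) * (wl - center) ** 2 / fwhm**2)
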