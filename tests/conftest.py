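import numpy as np
import pytest

from enamel_oct.phantom import (PhantomParams, constant_thickness,
                                elliptical_thickness, flat_surface,
                                generate_volume, parabolic_surface)


@pytest.fixture(scope="session")
def flat_phantom():
    """Noise-free piecewise-constant phantom: flat surface, full-span band."""
    params = PhantomParams(shape=(200, 96, 8),
                           surface_profile=flat_surface(100),
                           enamel_thickness_field=constant_thickness(70),
                           speckle_strength=0.0, seed=1)
    return params, generate_volume(params)


@pytest.fixture(scope="session")
def ellipse_phantom():
    """Noise-free phantom with an elliptical tooth footprint."""
    params = PhantomParams(shape=(220, 128, 64),
                           surface_profile=flat_surface(40),
                           enamel_thickness_field=elliptical_thickness(70, 0.8, 0.75),
                           speckle_strength=0.0, seed=2)
    return params, generate_volume(params)


@pytest.fixture(scope="session")
def speckled_phantom():
    """Moderately speckled phantom, small enough for fast unit tests."""
    params = PhantomParams(shape=(300, 128, 16),
                           surface_profile=parabolic_surface(60, 25, 10),
                           enamel_thickness_field=elliptical_thickness(80, 0.8, 0.75),
                           speckle_strength=0.15, seed=3)
    return params, generate_volume(params)
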