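import numpy as np
import pytest

from nectarct.phantom import (FlowerPhantomSpec, make_calibration_solid,
                              make_flower_phantom)


@pytest.fixture(scope="session")
def male_phantom():
    """Noiseless male flower: dome nectary of radius 20 vox at 5 um."""
    return make_flower_phantom(FlowerPhantomSpec(sex="male"))


@pytest.fixture(scope="session")
def female_phantom():
    """Noiseless female flower: annular nectary around a central style."""
    return make_flower_phantom(FlowerPhantomSpec(sex="female"))


@pytest.fixture(scope="session")
def noisy_male_phantom():
    """Male flower with additive noise at 5% of the tissue/air contrast."""
    spec = FlowerPhantomSpec(sex="male", noise_sd=0.05 * 20000, seed=7)
    return make_flower_phantom(spec)


@pytest.fixture(scope="session")
def sphere_solid():
    return make_calibration_solid("sphere", 20)


@pytest.fixture(scope="session")
def cube_solid():
    return make_calibration_solid("cube", 10)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
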