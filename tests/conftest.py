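import numpy as np
import pytest

from gaitpower import PUBLISHED_COEFFICIENTS, Sex, Subject


@pytest.fixture
def women_coeffs():
    return PUBLISHED_COEFFICIENTS[Sex.FEMALE]


@pytest.fixture
def men_coeffs():
    return PUBLISHED_COEFFICIENTS[Sex.MALE]


@pytest.fixture
def woman():
    return Subject(sex="female", mass_kg=57.0, height_m=1.61, age_yr=43.6)


@pytest.fixture
def man():
    return Subject(sex="male", mass_kg=74.0, height_m=1.75, age_yr=43.6)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
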