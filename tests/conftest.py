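import dataclasses

import numpy as np
import pytest

from vom.forcing import SyntheticClimateSpec, generate_synthetic_daily
from vom.presets import energy_limited_site, water_limited_site
from vom.sce import LongTermParams
from vom.soilwater import SOIL_TEXTURES, CatchmentGeometry


@pytest.fixture(scope="session")
def sandy_loam():
    return SOIL_TEXTURES["sandy loam"]


@pytest.fixture(scope="session")
def small_geometry():
    return CatchmentGeometry(z_surface=2.0, z_channel=0.5, slope_deg=2.0)


@pytest.fixture(scope="session")
def dry_site():
    return water_limited_site()


@pytest.fixture(scope="session")
def wet_site():
    return energy_limited_site()


@pytest.fixture(scope="session")
def default_lt():
    return LongTermParams(m_a_p=0.3, y_r_p=2.0, c_lambda_f_p=600.0,
                          c_lambda_e_p=-0.4, c_lambda_f_s=600.0,
                          c_lambda_e_s=-0.4)


@pytest.fixture(scope="session")
def one_year_weather(dry_site):
    climate = dataclasses.replace(dry_site.climate, rng_seed=42)
    return generate_synthetic_daily(climate, 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
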