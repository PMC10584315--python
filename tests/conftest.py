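from datetime import date

import pytest

from aquapot.engine import CropParameters
from aquapot.soil import SoilProfile
from aquapot.synthetic import (
    NINGXIA_ALTITUDE,
    NINGXIA_LATITUDE,
    ClimateSpec,
    generate_weather,
    load_fixture,
    ningxia_preset,
)
from aquapot.weather import SiteInfo, attach_et0


@pytest.fixture(scope="session")
def soil_profile() -> SoilProfile:
    return SoilProfile.from_frame(load_fixture("table3_soil"))


@pytest.fixture(scope="session")
def crop() -> CropParameters:
    return CropParameters()


@pytest.fixture(scope="session")
def site() -> SiteInfo:
    return SiteInfo(latitude=NINGXIA_LATITUDE, altitude=NINGXIA_ALTITUDE)


@pytest.fixture(scope="session")
def season_weather(site):
    """One synthetic year (2020) with ET0 attached."""
    wx = generate_weather(ningxia_preset(), years=1, start_year=2020, seed=42)
    return attach_et0(wx, site)


@pytest.fixture(scope="session")
def dry_weather(site):
    """A rain-free synthetic year: the crop lives on irrigation alone."""
    spec = ClimateSpec(rain_prob_by_month=(0.0,) * 12)
    wx = generate_weather(spec, years=1, start_year=2020, seed=42)
    return attach_et0(wx, site)


@pytest.fixture(scope="session")
def planting() -> date:
    return date(2020, 4, 30)
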