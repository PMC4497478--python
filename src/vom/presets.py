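"""Named synthetic sites and default search bounds.

The two desk-scale test sites contrast a strongly seasonal, dry climate
(annual potential evaporation well above rainfall) with a humid one, on a
shallow 3 m soil column so simulations stay fast.
"""
from __future__ import annotations

import dataclasses

from .forcing import SyntheticClimateSpec
from .soilwater import SOIL_TEXTURES, CatchmentGeometry, SoilHydraulicParams


@dataclasses.dataclass(frozen=True)
class SyntheticSite:
    name: str
    climate: SyntheticClimateSpec
    soil: SoilHydraulicParams
    geometry: CatchmentGeometry
    latitude_deg: float


def water_limited_site(rng_seed: int = 0) -> SyntheticSite:
    return SyntheticSite(
        name="synthetic-dry",
        climate=SyntheticClimateSpec(
            mean_annual_rain_mm=1100.0, wet_season_center=15,
            rain_seasonality=0.9, wet_day_prob=0.3, latitude_deg=-19.0,
            temperature_mean=26.0, temperature_amplitude=4.0,
            relative_humidity_mean=0.5, rng_seed=rng_seed),
        soil=SOIL_TEXTURES["sandy loam"],
        geometry=CatchmentGeometry(3.0, 0.5, 2.0, drain_length=100.0),
        latitude_deg=-19.0)


def energy_limited_site(rng_seed: int = 0) -> SyntheticSite:
    return SyntheticSite(
        name="synthetic-wet",
        climate=SyntheticClimateSpec(
            mean_annual_rain_mm=1800.0, wet_season_center=15,
            rain_seasonality=0.4, wet_day_prob=0.45, latitude_deg=-16.0,
            temperature_mean=24.0, temperature_amplitude=3.0,
            relative_humidity_mean=0.75, rng_seed=rng_seed),
        soil=SOIL_TEXTURES["sandy clay loam"],
        geometry=CatchmentGeometry(3.0, 0.5, 2.0, drain_length=100.0),
        latitude_deg=-16.0)


SYNTHETIC_SITES = {
    "water_limited": water_limited_site,
    "energy_limited": energy_limited_site,
}


def default_bounds(z_surface: float) -> list[tuple[float, float]]:
    """Search box for (M_A,p, y_r,p, c_f,p, c_e,p, c_f,s, c_e,s)."""
    return [(0.01, 1.0), (0.5, z_surface),
            (10.0, 3000.0), (-1.5, 0.3),
            (10.0, 3000.0), (-1.5, 0.3)]
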