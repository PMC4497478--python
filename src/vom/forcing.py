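"""Daily weather generation, file IO and hourly disaggregation.

The synthetic generator produces gridded-product-style daily series (rain,
global solar exposure, temperature extremes, vapour pressure) from a compact
climate specification; the disaggregator turns one daily record into 24 hourly
forcing records for the simulator. Years are 365 days long (no leap days).
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, FormatError

#: PPFD per unit global irradiance (mol quanta per J)
PPFD_PER_JOULE = 4.57e-6
#: atmospheric pressure used for mole-fraction deficits (kPa)
P_ATM_KPA = 101.325
DAYS_PER_YEAR = 365
#: hour of day (solar time) at which air temperature peaks
T_PEAK_HOUR = 14
_GSC = 0.0820  # solar constant, MJ m^-2 min^-1
_MAX_CLEARNESS = 0.75


@dataclasses.dataclass(frozen=True)
class DailyWeather:
    """One day of meteorological drivers."""

    date: _dt.date
    rain_mm: float
    i_g_daily: float  # global solar exposure, MJ m^-2 day^-1
    t_max: float      # degC
    t_min: float      # degC
    e_a: float        # vapour pressure, kPa

    def __post_init__(self) -> None:
        if self.rain_mm < 0 or self.i_g_daily < 0 or self.e_a < 0:
            raise DomainError("rain, irradiance and vapour pressure must be >= 0")
        if self.t_max < self.t_min:
            raise DomainError("t_max must be >= t_min")


@dataclasses.dataclass(frozen=True)
class HourlyForcing:
    """One hour of drivers as consumed by the simulator."""

    t: _dt.datetime
    i_a: float    # PPFD, mol quanta m^-2 s^-1
    t_a: float    # degC
    d_v: float    # vapour mole fraction deficit, mol mol^-1
    rain: float   # mm h^-1
    c_a: float    # atmospheric CO2, ppm


@dataclasses.dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of the synthetic daily weather generator."""

    mean_annual_rain_mm: float = 800.0
    wet_season_center: int = 15          # day of year
    rain_seasonality: float = 0.8        # 0..1 concentration of rain
    wet_day_prob: float = 0.25           # annual-mean wet-day probability
    mean_wet_day_depth_mm: Optional[float] = None  # derived if None
    latitude_deg: float = -15.0
    temperature_mean: float = 25.0
    temperature_amplitude: float = 5.0
    irradiance_clear_sky_fraction_range: tuple[float, float] = (0.5, 1.0)
    relative_humidity_mean: float = 0.6
    rain_persistence: float = 0.3        # first-order chain correlation
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_annual_rain_mm <= 0:
            raise ConfigurationError("mean_annual_rain_mm must be > 0")
        for name in ("rain_seasonality", "wet_day_prob",
                     "relative_humidity_mean", "rain_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.irradiance_clear_sky_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                "irradiance_clear_sky_fraction_range must be 0 <= lo <= hi <= 1")
        if not -90.0 < self.latitude_deg < 90.0:
            raise ConfigurationError("latitude_deg must be in (-90, 90)")
        if self.mean_wet_day_depth_mm is not None and self.mean_wet_day_depth_mm <= 0:
            raise ConfigurationError("mean_wet_day_depth_mm must be > 0")


class ReadResult(NamedTuple):
    days: list[DailyWeather]
    gaps: list[_dt.date]


def ppfd_from_irradiance(i_g: float) -> float:
    """PPFD (mol quanta m^-2 s^-1) from global irradiance (W m^-2)."""
    if np.any(np.asarray(i_g) < 0):
        raise DomainError("irradiance must be >= 0")
    return PPFD_PER_JOULE * i_g


def saturation_vapour_pressure(t_a: float) -> float:
    """Magnus-type saturation vapour pressure (kPa) at air temperature (degC)."""
    t_a = np.asarray(t_a, dtype=float)
    out = 0.6108 * np.exp(17.27 * t_a / (t_a + 237.3))
    return float(out) if out.ndim == 0 else out


def solar_geometry(latitude_deg: float, doy: int) -> tuple[float, float, float]:
    """(daylength h, sunrise h, extraterrestrial irradiation MJ m^-2 d^-1)."""
    phi = math.radians(latitude_deg)
    decl = math.radians(-23.45) * math.cos(2.0 * math.pi * (doy + 10) / DAYS_PER_YEAR)
    cos_ws = -math.tan(phi) * math.tan(decl)
    cos_ws = min(1.0, max(-1.0, cos_ws))
    ws = math.acos(cos_ws)
    daylength = 24.0 * ws / math.pi
    sunrise = 12.0 - daylength / 2.0
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / DAYS_PER_YEAR)
    ra = (24.0 * 60.0 / math.pi) * _GSC * dr * (
        ws * math.sin(phi) * math.sin(decl)
        + math.cos(phi) * math.cos(decl) * math.sin(ws))
    return daylength, sunrise, max(0.0, ra)


def _seasonal_cycle(doy: int, center: float, amplitude: float) -> float:
    return amplitude * math.cos(2.0 * math.pi * (doy - center) / DAYS_PER_YEAR)


def generate_synthetic_daily(spec: SyntheticClimateSpec,
                             n_years: int) -> list[DailyWeather]:
    """Generate ``n_years * 365`` days of synthetic weather.

    Rain occurrence follows a first-order two-state chain whose stationary
    wet probability tracks a seasonal cycle; wet-day depths are exponential
    with the mean chosen so the expected annual total matches the spec.
    """
    if n_years < 1:
        raise ConfigurationError("n_years must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    if spec.mean_wet_day_depth_mm is not None:
        mean_depth = spec.mean_wet_day_depth_mm
    elif spec.wet_day_prob > 0:
        mean_depth = spec.mean_annual_rain_mm / (DAYS_PER_YEAR * spec.wet_day_prob)
    else:
        mean_depth = 0.0
    rho = spec.rain_persistence
    lo, hi = spec.irradiance_clear_sky_fraction_range
    days: list[DailyWeather] = []
    wet_prev = False
    start = _dt.date(2000, 1, 1)
    for d in range(n_years * DAYS_PER_YEAR):
        doy = d % DAYS_PER_YEAR + 1
        p = spec.wet_day_prob * (
            1.0 + spec.rain_seasonality
            * math.cos(2.0 * math.pi * (doy - spec.wet_season_center) / DAYS_PER_YEAR))
        p = min(1.0, max(0.0, p))
        # chain balanced so its stationary wet frequency equals p
        p_cond = p + rho * (1.0 - p) if wet_prev else p * (1.0 - rho)
        wet = bool(rng.random() < p_cond) and mean_depth > 0
        rain = float(rng.exponential(mean_depth)) if wet else 0.0
        wet_prev = wet

        t_mean = (spec.temperature_mean
                  + _seasonal_cycle(doy, spec.wet_season_center,
                                    spec.temperature_amplitude)
                  + float(rng.normal(0.0, 1.0)))
        dtr = (6.0 if wet else 10.0) + float(rng.normal(0.0, 0.5))
        dtr = max(2.0, dtr)
        t_max = t_mean + dtr / 2.0
        t_min = t_mean - dtr / 2.0

        _, _, ra = solar_geometry(spec.latitude_deg, doy)
        frac = lo + (hi - lo) * float(rng.random())
        if wet:
            frac *= 0.6
        i_g = ra * _MAX_CLEARNESS * frac

        rh = spec.relative_humidity_mean + float(rng.uniform(-0.1, 0.1))
        rh = min(1.0, max(0.05, rh))
        e_a = max(0.01, rh * saturation_vapour_pressure(t_mean))

        days.append(DailyWeather(date=start + _dt.timedelta(days=d),
                                 rain_mm=rain, i_g_daily=i_g,
                                 t_max=t_max, t_min=t_min, e_a=e_a))
    return days


def _diurnal_temperature(t_min: float, t_max: float, hour: int,
                         dawn: int) -> float:
    """Piecewise sinusoid: minimum at dawn, maximum at T_PEAK_HOUR."""
    if dawn <= hour <= T_PEAK_HOUR:
        frac = (hour - dawn) / max(1, T_PEAK_HOUR - dawn)
        return t_min + (t_max - t_min) * math.sin(0.5 * math.pi * frac)
    hp = hour if hour > T_PEAK_HOUR else hour + 24
    frac = (hp - T_PEAK_HOUR) / max(1, dawn + 24 - T_PEAK_HOUR)
    return t_min + (t_max - t_min) * math.cos(0.5 * math.pi * frac)


def diurnal_irradiance_weights(latitude_deg: float, doy: int) -> np.ndarray:
    """Relative half-sine irradiance weights at the 24 hour centres; zero for
    hours whose centre lies outside daylight."""
    daylength, sunrise, _ = solar_geometry(latitude_deg, doy)
    w = np.zeros(24)
    if daylength <= 0:
        return w
    centres = np.arange(24) + 0.5
    inside = (centres > sunrise) & (centres < sunrise + daylength)
    w[inside] = np.sin(math.pi * (centres[inside] - sunrise) / daylength)
    return w


def disaggregate_to_hourly(day: DailyWeather, latitude_deg: float,
                           c_a: float) -> list[HourlyForcing]:
    """24 hourly records: even rain, energy-conserving half-sine irradiance,
    dawn-to-afternoon temperature sinusoid, constant vapour pressure."""
    doy = min(DAYS_PER_YEAR, day.date.timetuple().tm_yday)
    w = diurnal_irradiance_weights(latitude_deg, doy)
    wsum = w.sum()
    ig_w = np.zeros(24)
    if wsum > 0 and day.i_g_daily > 0:
        ig_w = day.i_g_daily * 1e6 * w / (wsum * 3600.0)  # W m^-2
    _, sunrise, _ = solar_geometry(latitude_deg, doy)
    dawn = int(round(sunrise))
    dawn = min(max(dawn, 1), T_PEAK_HOUR - 1)
    out = []
    for h in range(24):
        t_a = _diurnal_temperature(day.t_min, day.t_max, h, dawn)
        d_v = max(0.0, saturation_vapour_pressure(t_a) - day.e_a) / P_ATM_KPA
        out.append(HourlyForcing(
            t=_dt.datetime.combine(day.date, _dt.time(hour=h)),
            i_a=ppfd_from_irradiance(float(ig_w[h])),
            t_a=t_a, d_v=d_v, rain=day.rain_mm / 24.0, c_a=c_a))
    return out


# ---------------------------------------------------------------------------
# tabular IO

_COLUMNS = ("date", "rain_mm", "i_g_daily", "t_max", "t_min", "e_a")


def daily_to_frame(days: Sequence[DailyWeather]) -> pd.DataFrame:
    return pd.DataFrame(
        {"date": [d.date.isoformat() for d in days],
         "rain_mm": [d.rain_mm for d in days],
         "i_g_daily": [d.i_g_daily for d in days],
         "t_max": [d.t_max for d in days],
         "t_min": [d.t_min for d in days],
         "e_a": [d.e_a for d in days]})


def write_daily_weather(days: Sequence[DailyWeather], path) -> None:
    daily_to_frame(days).to_csv(path, index=False)


def read_daily_weather(path) -> ReadResult:
    """Read a headered daily-weather CSV; report missing calendar days."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty weather file: {path}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing columns in {path}: {missing}")
    if len(frame) == 0:
        raise FormatError(f"no rows in weather file: {path}")
    try:
        dates = [_dt.date.fromisoformat(str(s)) for s in frame["date"]]
    except ValueError as exc:
        raise FormatError(f"unparseable date in {path}: {exc}") from exc
    days = [DailyWeather(date=dates[i],
                         rain_mm=float(frame["rain_mm"].iloc[i]),
                         i_g_daily=float(frame["i_g_daily"].iloc[i]),
                         t_max=float(frame["t_max"].iloc[i]),
                         t_min=float(frame["t_min"].iloc[i]),
                         e_a=float(frame["e_a"].iloc[i]))
            for i in range(len(frame))]
    gaps: list[_dt.date] = []
    for prev, cur in zip(days, days[1:]):
        d = prev.date + _dt.timedelta(days=1)
        while d < cur.date:
            gaps.append(d)
            d += _dt.timedelta(days=1)
    return ReadResult(days=days, gaps=gaps)


def hourly_forcing_arrays(days: Sequence[DailyWeather], latitude_deg: float,
                          c_a: float):
    """Flatten a daily series into hourly numpy arrays for the simulator:
    (i_a mol m^-2 s^-1, t_a degC, d_v mol mol^-1, rain mm h^-1, i_g W m^-2).
    """
    n = len(days) * 24
    i_a = np.empty(n)
    t_a = np.empty(n)
    d_v = np.empty(n)
    rain = np.empty(n)
    ig_w = np.empty(n)
    for di, day in enumerate(days):
        hours = disaggregate_to_hourly(day, latitude_deg, c_a)
        for h, rec in enumerate(hours):
            t = di * 24 + h
            i_a[t] = rec.i_a
            t_a[t] = rec.t_a
            d_v[t] = rec.d_v
            rain[t] = rec.rain
            ig_w[t] = rec.i_a / PPFD_PER_JOULE
    return i_a, t_a, d_v, rain, ig_w
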