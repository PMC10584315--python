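"""Daily weather series and FAO-56 Penman-Monteith reference evapotranspiration.

A weather series is a :class:`pandas.DataFrame` with one row per day and the
fixed column set :data:`WEATHER_COLUMNS` (``et0`` optional until computed).
All sub-computations of the Penman-Monteith equation — saturation vapour
pressure, the slope of the vapour-pressure curve, the psychrometric constant,
extraterrestrial/net radiation from sunshine duration — follow the FAO
Irrigation and Drainage Paper 56 daily formulation.

Units: temperatures in degC, vapour pressures in kPa, radiation in
MJ m-2 day-1, wind at 2 m in m s-1, ET0 in mm day-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Solar constant, MJ m-2 min-1
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1
STEFAN_BOLTZMANN = 4.903e-9
#: Default grass reference albedo
DEFAULT_ALBEDO = 0.23
#: Default Angstrom coefficients (fraction of extraterrestrial radiation on
#: overcast days, and the additional fraction on clear days)
ANGSTROM_A = 0.25
ANGSTROM_B = 0.50

WEATHER_COLUMNS = [
    "date", "tmax", "tmin", "precip", "sunshine_hours", "rh_mean", "wind_u2",
]
OPTIONAL_COLUMNS = ["et0"]


@dataclass(frozen=True)
class SiteInfo:
    """Location metadata needed for radiation and pressure terms."""

    latitude: float  # decimal degrees, positive north
    altitude: float  # metres above sea level
    station_id: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")


@dataclass(frozen=True)
class PenmanTerms:
    """Inputs to the reference-evapotranspiration combination equation."""

    rn: float       # net radiation, MJ m-2 day-1
    g: float        # soil heat flux, MJ m-2 day-1
    t_mean: float   # mean air temperature at 2 m, degC
    u2: float       # wind speed at 2 m, m/s
    es: float       # saturation vapour pressure, kPa
    ea: float       # actual vapour pressure, kPa
    delta: float    # slope of vapour pressure curve, kPa/degC
    gamma: float    # psychrometric constant, kPa/degC

    def __post_init__(self) -> None:
        if self.ea < 0 or self.es < self.ea:
            raise ValueError("require es >= ea >= 0")
        if self.delta <= 0 or self.gamma <= 0:
            raise ValueError("delta and gamma must be positive")


class UnsupportedSiteError(ValueError):
    """Raised for sites/dates where the daily radiation model degenerates
    (polar day or night)."""


def saturation_vapour_pressure(t: float) -> float:
    """Saturation vapour pressure ``es`` (kPa) at air temperature ``t`` (degC),
    Tetens form 0.6108*exp(17.27 t / (t + 237.3))."""
    if t <= -40.0:
        raise ValueError(f"temperature {t} degC outside supported range")
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def slope_vapour_curve(t: float) -> float:
    """Slope of the saturation vapour-pressure curve (kPa/degC) at ``t``."""
    return 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2


def atmospheric_pressure(altitude: float) -> float:
    """Mean atmospheric pressure (kPa) at ``altitude`` m, standard atmosphere."""
    if altitude < -430.0:
        raise ValueError("altitude below supported range")
    return 101.3 * ((293.0 - 0.0065 * altitude) / 293.0) ** 5.26


def psychrometric_constant(altitude: float) -> float:
    """Psychrometric constant gamma (kPa/degC) from site altitude."""
    return 0.665e-3 * atmospheric_pressure(altitude)


def _solar_geometry(doy: int, latitude: float) -> tuple[float, float, float]:
    """Return (dr, declination, sunset hour angle) for day-of-year/latitude."""
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    dec = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    phi = math.radians(latitude)
    x = -math.tan(phi) * math.tan(dec)
    if x < -1.0 or x > 1.0:
        raise UnsupportedSiteError(
            f"polar day/night at latitude {latitude} on day {doy}: "
            "daily radiation model unsupported"
        )
    ws = math.acos(x)
    return dr, dec, ws


def extraterrestrial_radiation(doy: int, latitude: float) -> float:
    """Extraterrestrial radiation Ra (MJ m-2 day-1)."""
    dr, dec, ws = _solar_geometry(doy, latitude)
    phi = math.radians(latitude)
    return (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(dec)
        + math.cos(phi) * math.cos(dec) * math.sin(ws)
    )


def daylight_hours(doy: int, latitude: float) -> float:
    """Maximum possible sunshine duration N (h)."""
    _, _, ws = _solar_geometry(doy, latitude)
    return 24.0 / math.pi * ws


def net_radiation(
    doy: int,
    latitude: float,
    altitude: float,
    tmax: float,
    tmin: float,
    sunshine_hours: float,
    ea: float,
    albedo: float = DEFAULT_ALBEDO,
    angstrom_a: float = ANGSTROM_A,
    angstrom_b: float = ANGSTROM_B,
) -> float:
    """Daily net radiation Rn (MJ m-2 day-1) at the reference surface.

    Shortwave from the Angstrom sunshine-duration relation, net longwave from
    the Brunt-type emissivity and cloudiness correction.
    """
    ra = extraterrestrial_radiation(doy, latitude)
    n_max = daylight_hours(doy, latitude)
    n = min(max(sunshine_hours, 0.0), n_max)
    rs = (angstrom_a + angstrom_b * n / n_max) * ra
    rso = (0.75 + 2e-5 * altitude) * ra
    rns = (1.0 - albedo) * rs
    tmax_k, tmin_k = tmax + 273.16, tmin + 273.16
    cloudiness = min(rs / rso, 1.0) if rso > 0 else 1.0
    rnl = (
        STEFAN_BOLTZMANN
        * (tmax_k**4 + tmin_k**4) / 2.0
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * cloudiness - 0.35)
    )
    return rns - rnl


def et0_penman_monteith(terms: PenmanTerms) -> float:
    """Reference evapotranspiration (mm/day) from the daily combination
    equation; a negative radiative balance clamps the result to zero."""
    num = 0.408 * terms.delta * (terms.rn - terms.g) + terms.gamma * (
        900.0 / (terms.t_mean + 273.0)
    ) * terms.u2 * (terms.es - terms.ea)
    den = terms.delta + terms.gamma * (1.0 + 0.34 * terms.u2)
    et0 = num / den
    if et0 < 0.0:
        logger.warning("negative ET0 (%0.3f mm) clamped to 0", et0)
        return 0.0
    return et0


def penman_terms_for_day(
    date: pd.Timestamp,
    tmax: float,
    tmin: float,
    sunshine_hours: float,
    rh_mean: float,
    wind_u2: float,
    site: SiteInfo,
    albedo: float = DEFAULT_ALBEDO,
    angstrom_a: float = ANGSTROM_A,
    angstrom_b: float = ANGSTROM_B,
) -> PenmanTerms:
    """Assemble PenmanTerms for one day of raw meteorology.

    ``es`` is the mean of saturation pressures at the temperature extremes;
    ``ea`` reduces it by mean relative humidity; soil heat flux is taken as
    zero at the daily step.
    """
    t_mean = (tmax + tmin) / 2.0
    es = (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin)) / 2.0
    ea = min(rh_mean / 100.0 * es, es)
    doy = int(pd.Timestamp(date).dayofyear)
    rn = net_radiation(
        doy, site.latitude, site.altitude, tmax, tmin, sunshine_hours, ea,
        albedo=albedo, angstrom_a=angstrom_a, angstrom_b=angstrom_b,
    )
    return PenmanTerms(
        rn=rn, g=0.0, t_mean=t_mean, u2=wind_u2, es=es, ea=ea,
        delta=slope_vapour_curve(t_mean),
        gamma=psychrometric_constant(site.altitude),
    )


def validate_weather(df: pd.DataFrame) -> None:
    """Check the per-day physical invariants; raise ValueError naming the
    first offending date and field."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather series missing columns: {missing}")
    checks = [
        (df["tmax"] < df["tmin"], "tmax < tmin"),
        (df["precip"] < 0, "negative precip"),
        (~df["rh_mean"].between(0, 100), "rh_mean outside [0, 100]"),
        (df["wind_u2"] < 0, "negative wind_u2"),
        (~df["sunshine_hours"].between(0, 24), "sunshine_hours outside [0, 24]"),
    ]
    if "et0" in df.columns:
        checks.append((df["et0"].notna() & (df["et0"] < 0), "negative et0"))
    for bad, label in checks:
        for col in df.columns:
            if df[col].isna().any() and col != "et0":
                date = df.loc[df[col].isna(), "date"].iloc[0]
                raise ValueError(f"missing value in field '{col}' on {date}")
        if bad.any():
            date = df.loc[bad, "date"].iloc[0]
            raise ValueError(f"invalid weather on {date}: {label}")


def attach_et0(
    df: pd.DataFrame,
    site: SiteInfo,
    albedo: float = DEFAULT_ALBEDO,
    angstrom_a: float = ANGSTROM_A,
    angstrom_b: float = ANGSTROM_B,
    recompute: bool = False,
) -> pd.DataFrame:
    """Return a copy of the series with the ``et0`` column filled in.

    Days that already carry an ``et0`` value are left untouched unless
    ``recompute`` is set, so the operation is idempotent.
    """
    out = df.copy()
    if len(out) == 0:
        if "et0" not in out.columns:
            out["et0"] = pd.Series(dtype=float)
        return out
    validate_weather(out)
    if "et0" not in out.columns:
        out["et0"] = np.nan
    todo = out["et0"].isna() if not recompute else pd.Series(True, index=out.index)
    for idx in out.index[todo]:
        row = out.loc[idx]
        terms = penman_terms_for_day(
            row["date"], row["tmax"], row["tmin"], row["sunshine_hours"],
            row["rh_mean"], row["wind_u2"], site,
            albedo=albedo, angstrom_a=angstrom_a, angstrom_b=angstrom_b,
        )
        out.loc[idx, "et0"] = et0_penman_monteith(terms)
    return out


def read_weather_csv(path) -> pd.DataFrame:
    """Read a weather series CSV (ISO-8601 dates, fixed header)."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather CSV {path} missing columns: {missing}")
    return df


def write_weather_csv(df: pd.DataFrame, path) -> None:
    """Write a weather series CSV; empty fields (never NaN text) for gaps."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = WEATHER_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, na_rep="")
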