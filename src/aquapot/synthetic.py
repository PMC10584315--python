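"""Seeded synthetic inputs: arid-continental daily weather emulating the
central-Ningxia station climate, noisy observation series for exercising the
evaluation statistics, and the packaged result-table fixtures.

The weather generator is intentionally simple — monthly Bernoulli rain
occurrence with Gamma amounts, sinusoidal temperature normals with a shared
AR(1) anomaly, monthly relative-humidity normals, lognormal wind — because
the analysis only relies on seasonal totals and realistic evaporative
demand, not on spectral realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .weather import validate_weather

_FIXTURES = {
    "table1_treatments": "table1_treatments.csv",
    "table2_stage_allocation": "table2_stage_allocation.csv",
    "table3_soil": "table3_soil.csv",
    "table4_crop_params": "table4_crop_params.csv",
    "table5_scenarios": "table5_scenarios.csv",
    "table6_scenarioI": "table6_scenarioI.csv",
    "table7_scenarioII": "table7_scenarioII.csv",
}

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged result/parameter table by registry name."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    path = resources.files("aquapot.data") / _FIXTURES[name]
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def fixture_names() -> tuple[str, ...]:
    return tuple(sorted(_FIXTURES))


@dataclass(frozen=True)
class ClimateSpec:
    """Statistical targets and parameters of the daily weather generator.

    Monthly arrays run January..December. ``annual_rain_mm`` and
    ``may_oct_rain_mm`` are the targets the preset was designed around and
    are used by consistency checks, not directly by the sampler.
    """

    annual_rain_mm: float = 270.0
    may_oct_rain_mm: float = 250.0
    tmax_seasonal: tuple[float, float] = (14.5, 16.0)   # (mean, amplitude) degC
    tmin_seasonal: tuple[float, float] = (2.0, 15.0)    # (mean, amplitude) degC
    rain_prob_by_month: tuple[float, ...] = (
        0.01, 0.01, 0.02, 0.05, 0.13, 0.16, 0.20, 0.20, 0.15, 0.08, 0.02, 0.01,
    )
    rain_gamma: tuple[float, float] = (0.8, 10.6)       # (shape, scale) mm
    rh_by_month: tuple[float, ...] = (
        45, 42, 38, 35, 38, 42, 50, 55, 55, 50, 48, 47,
    )
    wind_lognorm: tuple[float, float] = (0.75, 0.40)    # (mu, sigma) of ln(u2)
    sunshine_frac: float = 0.68                          # fraction of daylength
    temp_anomaly_sd: float = 2.8                         # degC
    temp_anomaly_rho: float = 0.7
    diurnal_range_floor: float = 5.0                     # degC
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rain_prob_by_month) != 12 or len(self.rh_by_month) != 12:
            raise ValueError("monthly arrays must have 12 entries")
        if any(not 0.0 <= p <= 1.0 for p in self.rain_prob_by_month):
            raise ValueError("rain probabilities must lie in [0, 1]")
        if self.rain_gamma[0] <= 0 or self.rain_gamma[1] <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if self.tmax_seasonal[1] < 0 or self.tmin_seasonal[1] < 0:
            raise ValueError("seasonal amplitudes must be non-negative")
        if not 0.0 < self.sunshine_frac <= 1.0:
            raise ValueError("sunshine fraction must lie in (0, 1]")

    def expected_annual_rain(self) -> float:
        """Expected annual rainfall implied by the occurrence/amount model."""
        shape, scale = self.rain_gamma
        wet_days = float(np.dot(_DAYS_IN_MONTH, self.rain_prob_by_month))
        return wet_days * shape * scale

    def expected_may_oct_rain(self) -> float:
        shape, scale = self.rain_gamma
        wet = float(
            np.dot(_DAYS_IN_MONTH[4:10], self.rain_prob_by_month[4:10])
        )
        return wet * shape * scale


def ningxia_preset(seed: int = 0) -> ClimateSpec:
    """Preset for the arid central-Ningxia site (continental climate,
    ~270 mm mean annual rainfall concentrated May-October, large diurnal
    temperature range, high evaporative demand, 1489 m altitude)."""
    return ClimateSpec(seed=seed)


#: Site coordinates matching the preset (36.8 degN, 1489 m)
NINGXIA_LATITUDE = 36.8
NINGXIA_ALTITUDE = 1489.0


def _daylength_hours(doy: np.ndarray, latitude: float) -> np.ndarray:
    dec = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    phi = np.radians(latitude)
    x = np.clip(-np.tan(phi) * np.tan(dec), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(x)


def generate_weather(
    spec: ClimateSpec,
    years: int,
    start_year: int = 2015,
    latitude: float = NINGXIA_LATITUDE,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate ``years`` calendar years of daily weather (no Feb 29; each
    year has 365 days). Deterministic for a fixed seed."""
    if years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for y in range(start_year, start_year + years):
        dates = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
        dates = dates[~((dates.month == 2) & (dates.day == 29))]
        n = len(dates)
        doy = np.arange(1, n + 1)
        month = dates.month.to_numpy()

        # seasonal temperature normals peaking mid-July (doy 196)
        phase = np.cos(2.0 * np.pi * (doy - 196) / 365.0)
        tmax_norm = spec.tmax_seasonal[0] + spec.tmax_seasonal[1] * phase
        tmin_norm = spec.tmin_seasonal[0] + spec.tmin_seasonal[1] * phase
        anom = np.empty(n)
        eps = rng.normal(0.0, spec.temp_anomaly_sd, size=n)
        rho = spec.temp_anomaly_rho
        innov = (1.0 - rho**2) ** 0.5
        anom[0] = eps[0]
        for i in range(1, n):
            anom[i] = rho * anom[i - 1] + innov * eps[i]
        tmax = tmax_norm + anom
        tmin = tmin_norm + anom
        tmin = np.minimum(tmin, tmax - spec.diurnal_range_floor)

        p = np.array(spec.rain_prob_by_month)[month - 1]
        wet = rng.random(n) < p
        shape, scale = spec.rain_gamma
        amounts = rng.gamma(shape, scale, size=n)
        precip = np.where(wet, amounts, 0.0)

        rh = np.array(spec.rh_by_month, dtype=float)[month - 1]
        rh = np.clip(rh + rng.normal(0.0, 5.0, size=n) + 12.0 * wet, 5.0, 100.0)

        wind = np.exp(rng.normal(spec.wind_lognorm[0], spec.wind_lognorm[1], size=n))
        daylen = _daylength_hours(doy, latitude)
        sun = np.clip(
            daylen * (spec.sunshine_frac + rng.normal(0.0, 0.12, size=n))
            * np.where(wet, 0.45, 1.0),
            0.0, daylen,
        )

        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "tmax": tmax,
                    "tmin": tmin,
                    "precip": precip,
                    "sunshine_hours": sun,
                    "rh_mean": rh,
                    "wind_u2": wind,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    validate_weather(out)
    return out



def generate_observations(
    truth: pd.Series,
    noise_sd: float,
    sampling_dates,
    variable: str = "canopy_cover",
    seed: int = 0,
    clip: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Noisy "measurements" of a simulated daily trajectory.

    ``truth`` is a Series indexed by date; observations are truth at the
    sampling dates plus iid Gaussian noise, clipped to the variable's
    validity range (canopy cover [0, 100] %, biomass non-negative).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    idx = pd.DatetimeIndex(pd.to_datetime(list(sampling_dates)))
    missing = idx.difference(pd.DatetimeIndex(truth.index))
    if len(missing):
        raise ValueError(f"sampling date {missing[0].date()} outside the truth span")
    rng = np.random.default_rng(seed)
    values = truth.loc[idx].to_numpy(dtype=float)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    if clip is None:
        clip = (0.0, 100.0) if variable == "canopy_cover" else (0.0, np.inf)
    values = np.clip(values, clip[0], clip[1])
    return pd.DataFrame({"date": idx, "variable": variable, "value": values})
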