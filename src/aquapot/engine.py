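"""Daily water-driven production chain and the season simulation.

Transpiration follows Tr = Ks (CC* KcTr,x) ET0; above-ground biomass
accumulates as B = WP* sum(Tr/ET0) with WP* the normalized water
productivity; tuber yield is Y = fHI HI0 B; water use efficiency is
WUE = Y/ET with ET the seasonal soil evaporation plus transpiration.

The season loop couples the canopy clock (thermal time, water-stress
modulated) with the layered soil bucket: each day the soil first takes
rain and irrigation, then stress coefficients are read from root-zone
depletion, the canopy advances, and evaporation/transpiration demands are
extracted subject to availability. Biomass uses realized (post-cap)
transpiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .canopy import CanopyParams, CanopyState, adjust_cc_star, canopy_step, gdd
from .irrigation import IrrigationPlan
from .soil import (
    SoilProfile,
    StressThresholds,
    initial_state,
    root_zone_depletion,
    soil_water_step,
    storage_mm,
    stress_coefficient,
    total_available_water,
    update_root_depth,
)

#: g/m2 -> t/ha
G_M2_TO_T_HA = 0.01
#: soil-evaporation coefficient for wet bare soil
DEFAULT_KE = 1.10


@dataclass(frozen=True)
class CropStressThresholds:
    """The three depletion-threshold responses of the calibrated crop."""

    expansion: StressThresholds = field(
        default_factory=lambda: StressThresholds(p_upper=0.26, p_lower=0.66)
    )
    stomatal: StressThresholds = field(
        default_factory=lambda: StressThresholds(p_upper=0.65, p_lower=1.0)
    )
    senescence: StressThresholds = field(
        default_factory=lambda: StressThresholds(p_upper=0.69, p_lower=1.0)
    )


@dataclass(frozen=True)
class CropParameters:
    """Calibrated crop parameters for drip-irrigated potato."""

    kc_tr_x: float = 1.15        # maximum crop transpiration coefficient
    wp_star: float = 20.0        # normalized water productivity, g/m2
    hi0: float = 55.0            # reference harvest index, %
    canopy: CanopyParams = field(default_factory=CanopyParams)
    thresholds: CropStressThresholds = field(default_factory=CropStressThresholds)
    z_min: float = 0.20          # initial effective root depth, m
    z_max: float = 0.45          # maximum effective root depth, m
    root_days_to_max: int = 75
    dm_fraction: float = 0.11    # tuber dry-matter fraction (fresh = dry/dm)
    f_hi_policy: str = "none"    # harvest-index stress adjustment hook
    ke: float = DEFAULT_KE       # soil evaporation coefficient
    wetted_fraction: float = 0.30  # surface fraction wetted under drip
    cc_star_policy: str = "micro_advective"

    def __post_init__(self) -> None:
        if not 0.0 < self.hi0 <= 100.0:
            raise ValueError("hi0 must be in (0, 100]")
        if self.wp_star <= 0:
            raise ValueError("wp_star must be positive")
        if not 0.0 < self.dm_fraction <= 1.0:
            raise ValueError("dm_fraction must be in (0, 1]")


def default_crop_parameters() -> CropParameters:
    """The calibrated potato parameter set."""
    return CropParameters()


@dataclass(frozen=True)
class SimulationResult:
    daily: pd.DataFrame          # one row per simulated day
    biomass_final: float         # t/ha dry above-ground biomass
    yield_dry: float             # t/ha
    yield_fresh: float           # t/ha fresh tuber
    et_total: float              # mm, E + Tr over the season
    e_total: float               # mm
    tr_total: float              # mm
    wue: float                   # kg tuber per m3 water consumed
    irrigation_total: float      # mm
    rain_total: float            # mm
    drainage_total: float        # mm
    f_hi: float


def transpiration(ks: float, cc_star: float, kc_tr_x: float, et0: float) -> float:
    """Daily crop transpiration demand (mm): Tr = Ks (CC* KcTr,x) ET0."""
    for name, v in (("ks", ks), ("cc_star", cc_star)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if et0 < 0 or kc_tr_x < 0:
        raise ValueError("et0 and kc_tr_x must be non-negative")
    return ks * cc_star * kc_tr_x * et0


def biomass_increment(wp_star: float, tr: float, et0: float) -> float:
    """Daily biomass gain (t/ha): WP* (g/m2) times the normalized
    transpiration Tr/ET0; zero on no-demand days (ET0 = 0)."""
    if tr < 0:
        raise ValueError("transpiration must be non-negative")
    if et0 <= 0:
        return 0.0
    return G_M2_TO_T_HA * wp_star * tr / et0


def f_hi_factor(policy: str = "none") -> float:
    """Harvest-index adjustment factor fHI. The default policy applies no
    stress adjustment (fHI = 1); the hook exists for stress-modulated HI."""
    if policy in ("none", "identity"):
        return 1.0
    raise ValueError(f"unknown fHI policy {policy!r}")


def yield_from_biomass(
    b: float, hi0: float, f_hi: float = 1.0, dm_fraction: float = 0.11
) -> tuple[float, float]:
    """(dry, fresh) tuber yield in t/ha: Y_dry = fHI (HI0/100) B and
    Y_fresh = Y_dry / dm_fraction."""
    if b < 0 or hi0 < 0:
        raise ValueError("biomass and hi0 must be non-negative")
    if not 0.0 <= f_hi <= 1.2:
        raise ValueError("f_hi must be in [0, 1.2]")
    if dm_fraction <= 0:
        raise ValueError("dm_fraction must be positive")
    y_dry = f_hi * hi0 / 100.0 * b
    return y_dry, y_dry / dm_fraction


def water_use_efficiency(y_fresh: float, et_total: float) -> float:
    """WUE (kg/m3) = yield / water consumed; with Y in t/ha and ET in mm this
    reduces to 100 Y / ET (1 t/ha = 1000 kg/ha, 1 mm = 10 m3/ha)."""
    if et_total <= 0:
        raise ValueError("seasonal ET must be positive")
    if y_fresh < 0:
        raise ValueError("yield must be non-negative")
    return 100.0 * y_fresh / et_total


def run_simulation(
    weather: pd.DataFrame,
    soil: SoilProfile,
    crop: CropParameters,
    plan: IrrigationPlan,
    planting_date: date,
    season_days: int | None = None,
    initial_condition: str | float = "fc",
) -> SimulationResult:
    """Simulate one growing season at a daily step.

    ``weather`` must carry an ``et0`` column (see ``weather.attach_et0``)
    and cover planting through maturity without gaps. Deterministic: equal
    inputs give identical results.
    """
    n_days = season_days or crop.canopy.maturity_day
    wx = weather.copy()
    wx["date"] = pd.to_datetime(wx["date"])
    wx = wx.set_index("date")
    if "et0" not in wx.columns or wx["et0"].isna().any():
        raise ValueError("weather must have et0 attached for every day")

    start = pd.Timestamp(planting_date)
    span = pd.date_range(start, start + pd.Timedelta(days=n_days - 1), freq="D")
    missing = span.difference(wx.index)
    if len(missing):
        raise ValueError(f"weather gap: no data for {missing[0].date()}")

    state = initial_state(soil, crop.z_min, condition=initial_condition)
    can = CanopyState()
    biomass = 0.0
    rows = []
    rain_total = irr_total = 0.0

    for day_index, ts in enumerate(span):
        w = wx.loc[ts]
        et0 = float(w["et0"])
        rain = float(w["precip"])
        irr = plan.depth_on(ts.date())

        state.root_depth = update_root_depth(
            day_index, crop.z_min, crop.z_max, crop.root_days_to_max
        )
        # water in first: today's rain/irrigation relieves today's stress
        state, fluxes_in = soil_water_step(state, soil, rain=rain, irrigation=irr)

        taw = total_available_water(soil, state.root_depth)
        dr = root_zone_depletion(state, soil)
        ks_exp = stress_coefficient(dr, taw, crop.thresholds.expansion)
        ks_sto = stress_coefficient(dr, taw, crop.thresholds.stomatal)
        ks_sen = stress_coefficient(dr, taw, crop.thresholds.senescence)

        dgdd = gdd(
            float(w["tmax"]), float(w["tmin"]),
            crop.canopy.t_base, crop.canopy.t_upper,
        )
        can = canopy_step(
            can, crop.canopy, dgdd, day_index, ks_exp=ks_exp, ks_sen=ks_sen
        )
        cc_star = adjust_cc_star(can.cc, crop.cc_star_policy)

        tr_demand = transpiration(ks_sto, cc_star, crop.kc_tr_x, et0)
        # soil evaporation only from the exposed wetted surface: under drip
        # the emitters wet a fraction of the ground, so bare-soil evaporative
        # demand is scaled by that fraction
        e_demand = crop.wetted_fraction * crop.ke * (1.0 - can.cc) * et0
        state, fluxes = soil_water_step(
            state, soil, e_demand=e_demand, tr_demand=tr_demand
        )

        b_inc = biomass_increment(crop.wp_star, fluxes.tr_realized, et0)
        biomass += b_inc
        rain_total += rain
        irr_total += irr
        rows.append(
            {
                "date": ts, "et0": et0, "rain": rain, "irrigation": irr,
                "e": fluxes.e_realized, "tr": fluxes.tr_realized,
                "drainage": fluxes_in.drainage + fluxes.drainage,
                "cc": can.cc, "phase": can.phase,
                "gdd_cum": can.gdd_cum, "root_depth": state.root_depth,
                "taw": taw, "dr": dr, "ks_exp": ks_exp, "ks_sto": ks_sto,
                "ks_sen": ks_sen, "b_inc": b_inc, "b_cum": biomass,
                "storage": storage_mm(state, soil),
            }
        )

    daily = pd.DataFrame(rows)
    f_hi = f_hi_factor(crop.f_hi_policy)
    y_dry, y_fresh = yield_from_biomass(
        biomass, crop.hi0, f_hi=f_hi, dm_fraction=crop.dm_fraction
    )
    e_total = float(daily["e"].sum())
    tr_total = float(daily["tr"].sum())
    et_total = e_total + tr_total
    wue = water_use_efficiency(y_fresh, et_total) if et_total > 0 else 0.0
    return SimulationResult(
        daily=daily, biomass_final=biomass, yield_dry=y_dry,
        yield_fresh=y_fresh, et_total=et_total, e_total=e_total,
        tr_total=tr_total, wue=wue, irrigation_total=irr_total,
        rain_total=rain_total, drainage_total=float(daily["drainage"].sum()),
        f_hi=f_hi,
    )


def daily_to_csv(result: SimulationResult, path) -> None:
    """Write the per-day trajectory in the documented results dialect."""
    out = result.daily[
        ["date", "et0", "e", "tr", "cc", "dr", "ks_sto", "b_cum"]
    ].copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def season_summary(result: SimulationResult, label: str = "") -> dict:
    return {
        "scheme": label,
        "yield_t_ha": result.yield_fresh,
        "biomass_t_ha": result.biomass_final,
        "wue_kg_m3": result.wue,
        "et_mm": result.et_total,
        "irrigation_mm": result.irrigation_total,
        "rain_mm": result.rain_total,
    }
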