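"""Layered-bucket soil water balance for the root zone under drip irrigation.

The profile is an ordered stack of contiguous layers with measured hydraulic
limits (wilting point, field capacity, saturation). Each day, infiltration
(rain + drip irrigation) enters the top layer and cascades instantaneously:
any water above field capacity passes to the layer below and finally out of
the profile as deep drainage. Soil evaporation is drawn from the top layer
down to an air-dry floor of half the wilting point; transpiration is drawn
from the rooted zone down to the wilting point, proportionally to each
layer's available water. Water-stress coefficients are piecewise functions
of root-zone depletion relative to total available water (TAW).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MM_PER_CM = 10.0
#: Air-dry water content of the evaporating layer, as a fraction of theta_wp
AIR_DRY_FRACTION = 0.5
#: Readily evaporable water (mm) before the falling-rate drying stage
DEFAULT_REW_MM = 8.0
#: Depth of the surface skin that supplies soil evaporation (m)
DEFAULT_EVAP_DEPTH_M = 0.10


@dataclass(frozen=True)
class SoilLayer:
    top_cm: float
    bottom_cm: float
    theta_wp: float   # wilting point, cm3/cm3
    theta_fc: float   # field capacity, cm3/cm3
    theta_sat: float  # saturation, cm3/cm3
    bulk_density: float = 1.4  # g/cm3

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_wp < self.theta_fc < self.theta_sat < 1.0:
            raise ValueError(
                f"require 0 < wp < fc < sat < 1, got "
                f"({self.theta_wp}, {self.theta_fc}, {self.theta_sat})"
            )
        if self.bottom_cm <= self.top_cm:
            raise ValueError("layer bottom must lie below its top")

    @property
    def thickness_mm(self) -> float:
        return (self.bottom_cm - self.top_cm) * MM_PER_CM


@dataclass(frozen=True)
class SoilProfile:
    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if self.layers[0].top_cm != 0.0:
            raise ValueError("profile must start at the surface (0 cm)")
        for upper, lower in zip(self.layers, self.layers[1:]):
            if lower.top_cm != upper.bottom_cm:
                raise ValueError("layers must be contiguous")

    @property
    def depth_m(self) -> float:
        return self.layers[-1].bottom_cm / 100.0

    def root_fractions(self, root_depth: float) -> np.ndarray:
        """Fraction of each layer's thickness inside the root zone."""
        if root_depth > self.depth_m + 1e-12:
            raise ValueError(
                f"root depth {root_depth} m exceeds profile depth {self.depth_m} m"
            )
        root_cm = root_depth * 100.0
        fr = np.zeros(len(self.layers))
        for i, lay in enumerate(self.layers):
            overlap = min(root_cm, lay.bottom_cm) - lay.top_cm
            fr[i] = max(overlap, 0.0) / (lay.bottom_cm - lay.top_cm)
        return fr

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SoilProfile":
        layers = tuple(
            SoilLayer(
                top_cm=row["top_cm"], bottom_cm=row["bottom_cm"],
                theta_wp=row["theta_wp"], theta_fc=row["theta_fc"],
                theta_sat=row["theta_sat"],
                bulk_density=row.get("bulk_density", 1.4),
            )
            for _, row in df.iterrows()
        )
        return cls(layers)

    @classmethod
    def from_csv(cls, path) -> "SoilProfile":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class StressThresholds:
    """Depletion thresholds (fractions of TAW) bracketing a stress response."""

    p_upper: float
    p_lower: float = 1.0
    shape: str = "linear"  # or "convex"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_upper < self.p_lower <= 1.0:
            raise ValueError(
                f"require 0 <= p_upper < p_lower <= 1, got "
                f"({self.p_upper}, {self.p_lower})"
            )
        if self.shape not in ("linear", "convex"):
            raise ValueError(f"unknown stress shape {self.shape!r}")


@dataclass
class WaterState:
    """Volumetric water content per layer plus cumulative season fluxes."""

    theta: np.ndarray          # cm3/cm3 per layer
    root_depth: float          # m
    drainage_cum: float = 0.0  # mm
    e_cum: float = 0.0         # mm soil evaporation
    tr_cum: float = 0.0        # mm transpiration

    def copy(self) -> "WaterState":
        return WaterState(
            theta=self.theta.copy(), root_depth=self.root_depth,
            drainage_cum=self.drainage_cum, e_cum=self.e_cum,
            tr_cum=self.tr_cum,
        )


@dataclass(frozen=True)
class StepFluxes:
    """Realized water fluxes for one daily step (all mm)."""

    infiltration: float
    drainage: float
    e_realized: float
    tr_realized: float


def initial_state(
    profile: SoilProfile, root_depth: float, condition: str | float = "fc"
) -> WaterState:
    """State at planting: ``'fc'`` fills the profile to field capacity, a
    float f in [0, 1] fills to wp + f*(fc - wp)."""
    if condition == "fc":
        theta = np.array([lay.theta_fc for lay in profile.layers])
    else:
        f = float(condition)
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractional initial condition must be in [0, 1]")
        theta = np.array(
            [lay.theta_wp + f * (lay.theta_fc - lay.theta_wp) for lay in profile.layers]
        )
    return WaterState(theta=theta, root_depth=root_depth)


def storage_mm(state: WaterState, profile: SoilProfile) -> float:
    """Total profile water storage (mm)."""
    return float(
        sum(t * lay.thickness_mm for t, lay in zip(state.theta, profile.layers))
    )


def total_available_water(profile: SoilProfile, root_depth: float) -> float:
    """TAW (mm): water held between field capacity and wilting point over the
    root zone."""
    fr = profile.root_fractions(root_depth)
    return float(
        sum(
            (lay.theta_fc - lay.theta_wp) * lay.thickness_mm * f
            for lay, f in zip(profile.layers, fr)
        )
    )


def root_zone_depletion(
    state: WaterState, profile: SoilProfile, root_depth: float | None = None
) -> float:
    """Depletion Dr (mm) below field capacity over the root zone, floored at 0."""
    rd = state.root_depth if root_depth is None else root_depth
    fr = profile.root_fractions(rd)
    dr = sum(
        max(lay.theta_fc - t, 0.0) * lay.thickness_mm * f
        for t, lay, f in zip(state.theta, profile.layers, fr)
    )
    return float(dr)


def stress_coefficient(
    dr: float, taw: float, thresholds: StressThresholds
) -> float:
    """Water-stress coefficient Ks in [0, 1].

    Ks = 1 while relative depletion Dr/TAW stays below the upper threshold,
    0 beyond the lower threshold, and decreases (linearly, or convexly for
    the ``convex`` shape) in between.
    """
    if taw <= 0:
        raise ValueError("TAW must be positive")
    if dr < 0:
        raise ValueError("depletion must be non-negative")
    p_rel = dr / taw
    if p_rel <= thresholds.p_upper:
        return 1.0
    if p_rel >= thresholds.p_lower:
        return 0.0
    s = (p_rel - thresholds.p_upper) / (thresholds.p_lower - thresholds.p_upper)
    if thresholds.shape == "convex":
        k = 3.0
        return 1.0 - float(np.expm1(k * s) / np.expm1(k))
    return 1.0 - s


def update_root_depth(
    day_index: int, z_min: float = 0.20, z_max: float = 0.45,
    days_to_max: int = 75,
) -> float:
    """Effective rooting depth (m): linear ramp from z_min at planting to
    z_max by ``days_to_max`` days after planting."""
    if day_index < 0:
        raise ValueError("day index must be non-negative")
    if day_index >= days_to_max:
        return z_max
    return z_min + (z_max - z_min) * day_index / days_to_max


def soil_water_step(
    state: WaterState,
    profile: SoilProfile,
    rain: float = 0.0,
    irrigation: float = 0.0,
    e_demand: float = 0.0,
    tr_demand: float = 0.0,
    rew_mm: float = DEFAULT_REW_MM,
    evap_depth_m: float = DEFAULT_EVAP_DEPTH_M,
) -> tuple[WaterState, StepFluxes]:
    """Advance the bucket balance one day; returns the new state and realized
    fluxes. Demands are capped by available water, never rejected; the water
    balance closes exactly (Delta storage = in - drainage - E - Tr)."""
    for name, v in (("rain", rain), ("irrigation", irrigation),
                    ("e_demand", e_demand), ("tr_demand", tr_demand)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    theta = state.theta.copy()
    layers = profile.layers

    # infiltration: drip/rain water enters the top layer, excess over field
    # capacity cascades downward, leftovers leave as deep drainage
    carry = rain + irrigation
    drainage = 0.0
    for i, lay in enumerate(layers):
        theta[i] += carry / lay.thickness_mm
        excess = max(theta[i] - lay.theta_fc, 0.0) * lay.thickness_mm
        theta[i] = min(theta[i], lay.theta_fc)
        carry = excess
    drainage = carry

    # soil evaporation from a thin surface skin of the top layer, two-stage:
    # full rate within the readily-evaporable depletion, then linear falling
    # rate to air dry
    top = layers[0]
    air_dry = AIR_DRY_FRACTION * top.theta_wp
    skin_mm = min(evap_depth_m * 1000.0, top.thickness_mm)
    evap_capacity = (top.theta_fc - air_dry) * skin_mm
    evap_available = max((theta[0] - air_dry) * skin_mm, 0.0)
    depletion_e = evap_capacity - evap_available
    if depletion_e <= rew_mm:
        kr = 1.0
    elif evap_capacity > rew_mm:
        kr = max(evap_available / (evap_capacity - rew_mm), 0.0)
    else:
        kr = 0.0
    e_real = min(e_demand * kr, evap_available)
    theta[0] -= e_real / top.thickness_mm

    # transpiration from the rooted zone, proportional to available water
    fr = profile.root_fractions(state.root_depth)
    avail = np.array(
        [
            max(t - lay.theta_wp, 0.0) * lay.thickness_mm * f
            for t, lay, f in zip(theta, layers, fr)
        ]
    )
    total_avail = float(avail.sum())
    tr_real = min(tr_demand, total_avail)
    if tr_real > 0 and total_avail > 0:
        for i, lay in enumerate(layers):
            take = tr_real * avail[i] / total_avail
            theta[i] -= take / lay.thickness_mm

    new_state = WaterState(
        theta=theta,
        root_depth=state.root_depth,
        drainage_cum=state.drainage_cum + drainage,
        e_cum=state.e_cum + e_real,
        tr_cum=state.tr_cum + tr_real,
    )
    fluxes = StepFluxes(
        infiltration=rain + irrigation, drainage=drainage,
        e_realized=e_real, tr_realized=tr_real,
    )
    return new_state, fluxes
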