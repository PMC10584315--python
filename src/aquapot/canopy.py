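"""Green canopy-cover development on a thermal-time clock.

Canopy cover (CC, fraction of shaded ground) grows exponentially from the
initial seedling cover CC0, decelerates past half the maximum cover CCx,
plateaus at CCx, and declines after senescence. Growth and decline both run
on growing degree days (GDD) with the canopy growth coefficient CGC and
canopy decline coefficient CDC expressed per degree-day. Water stress slows
expansion (Ks_exp scales CGC) and, once depletion crosses the senescence
threshold, triggers early decline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

PHASES = ("pre_emergence", "growth", "max", "senescence", "mature")

#: Snap tolerance: once cover is this close to CCx the plateau is reached
PLATEAU_SNAP = 1e-4


@dataclass(frozen=True)
class CanopyParams:
    """Canopy development parameters (percent units as conventionally tabulated)."""

    cc0: float = 0.9       # initial canopy cover, %
    cgc: float = 0.966     # canopy growth coefficient, %/GDD
    ccx: float = 94.0      # maximum canopy cover, %
    cdc: float = 0.798     # canopy decline coefficient, %/GDD
    t_base: float = 10.0   # degC
    t_upper: float = 35.0  # degC
    emergence_day: int = 0
    max_canopy_day: int = 110
    senescence_day: int = 120
    maturity_day: int = 150

    def __post_init__(self) -> None:
        if not 0.0 < self.cc0 < self.ccx <= 100.0:
            raise ValueError("require 0 < cc0 < ccx <= 100")
        if self.cgc <= 0 or self.cdc <= 0:
            raise ValueError("cgc and cdc must be positive")
        if self.t_base >= self.t_upper:
            raise ValueError("t_base must be below t_upper")

    @property
    def cc0_frac(self) -> float:
        return self.cc0 / 100.0

    @property
    def ccx_frac(self) -> float:
        return self.ccx / 100.0

    @property
    def cgc_frac(self) -> float:
        return self.cgc / 100.0

    @property
    def cdc_frac(self) -> float:
        return self.cdc / 100.0


@dataclass
class CanopyState:
    cc: float = 0.0               # green cover fraction [0, 1]
    phase: str = "pre_emergence"
    gdd_cum: float = 0.0          # degC day since planting
    gdd_senescence: float = 0.0   # degC day since senescence onset
    cc_at_senescence: float = 0.0


def lai_to_cc(lai: float) -> float:
    """Convert leaf area index to canopy-cover fraction,
    CC = 1.005 [1 - exp(-0.6 LAI)]^1.2, capped at 1."""
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    return min(1.005 * (1.0 - math.exp(-0.6 * lai)) ** 1.2, 1.0)


def gdd(tmax: float, tmin: float, t_base: float = 10.0, t_upper: float = 35.0) -> float:
    """Growing degree days for one day: temperature extremes are capped at
    the upper limit, and the excess of their mean over the base temperature
    is floored at zero."""
    if tmax < tmin:
        raise ValueError("tmax must not be below tmin")
    t_mean = (min(tmax, t_upper) + min(tmin, t_upper)) / 2.0
    return max(t_mean - t_base, 0.0)


def adjust_cc_star(cc: float, policy: str = "micro_advective") -> float:
    """Adjusted canopy cover CC* used for transpiration.

    The ``micro_advective`` policy inflates partial covers for the extra
    evaporative demand intercepted by row crops
    (CC* = 1.72 CC - CC^2 + 0.30 CC^3); ``identity`` returns CC unchanged.
    """
    if not 0.0 <= cc <= 1.0:
        raise ValueError("cc must be a fraction in [0, 1]")
    if policy == "identity":
        return cc
    if policy == "micro_advective":
        return min(max(1.72 * cc - cc * cc + 0.30 * cc**3, 0.0), 1.0)
    raise ValueError(f"unknown CC* policy {policy!r}")


def canopy_step(
    state: CanopyState,
    params: CanopyParams,
    dgdd: float,
    day_index: int,
    ks_exp: float = 1.0,
    ks_sen: float = 1.0,
) -> CanopyState:
    """Advance the canopy one day.

    Growth phase (before the senescence day): dCC = CGC_eff * dGDD * CC for
    CC <= CCx/2, switching to the mirrored deceleration
    dCC = CGC_eff * dGDD * (CCx - CC), with CGC_eff = Ks_exp * CGC; cover
    snaps to CCx once within PLATEAU_SNAP. Severe depletion (Ks_sen < 1)
    superimposes early decline with CDC scaled by (1 - Ks_sen). After the
    senescence day, cover declines along the canonical decay curve on the
    thermal clock accumulated since onset.
    """
    if dgdd < 0:
        raise ValueError("dgdd must be non-negative")
    if not 0.0 <= ks_exp <= 1.0 or not 0.0 <= ks_sen <= 1.0:
        raise ValueError("stress coefficients must be in [0, 1]")
    new = CanopyState(
        cc=state.cc, phase=state.phase, gdd_cum=state.gdd_cum + dgdd,
        gdd_senescence=state.gdd_senescence,
        cc_at_senescence=state.cc_at_senescence,
    )
    ccx = params.ccx_frac

    if day_index < params.emergence_day:
        new.phase = "pre_emergence"
        return new

    if new.phase == "pre_emergence":
        new.phase = "growth"
        new.cc = params.cc0_frac
        return new  # emergence day: cover starts at exactly CC0

    in_senescence_window = day_index >= params.senescence_day
    if in_senescence_window and new.phase in ("growth", "max"):
        new.phase = "senescence"
        new.cc_at_senescence = max(new.cc, 1e-6)

    if new.phase == "senescence":
        new.gdd_senescence += dgdd
        ccref = new.cc_at_senescence
        # decline rate from the canonical decay curve expressed in terms of
        # the current cover: dCC/dGDD = -0.05 CDC (21 - 20 CC/CCref)
        rate = 0.05 * params.cdc_frac * max(21.0 - 20.0 * new.cc / ccref, 1.0)
        new.cc = max(new.cc - rate * dgdd, 0.0)
        if new.cc <= 0.0 or day_index >= params.maturity_day:
            new.phase = "mature" if new.cc <= 0.0 else new.phase
    elif new.phase in ("growth", "max"):
        if new.cc <= ccx / 2.0:
            dcc = params.cgc_frac * ks_exp * dgdd * new.cc
        else:
            dcc = params.cgc_frac * ks_exp * dgdd * (ccx - new.cc)
        new.cc = min(new.cc + dcc, ccx)
        if ccx - new.cc <= PLATEAU_SNAP:
            new.cc = ccx
            new.phase = "max"
        # water-stress-triggered early senescence: decay proportional to the
        # current cover at CDC scaled by (1 - Ks_sen), so a rewetted crop can
        # regrow from whatever green cover survives the dry spell
        if ks_sen < 1.0:
            new.cc = max(
                new.cc * (1.0 - params.cdc_frac * (1.0 - ks_sen) * dgdd), 0.0
            )
            if new.phase == "max" and new.cc < ccx:
                new.phase = "growth"

    if day_index >= params.maturity_day:
        new.phase = "mature"
    return new
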