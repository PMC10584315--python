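"""Straight-line reference implementation of the daily FAO-56 reference
evapotranspiration chain, written independently of the package for use as a
test oracle: every sub-step is evaluated inline, spreadsheet style."""

import math


def reference_et0(
    doy: int,
    latitude_deg: float,
    altitude_m: float,
    tmax: float,
    tmin: float,
    sunshine_hours: float,
    rh_mean: float,
    u2: float,
    albedo: float = 0.23,
    a_s: float = 0.25,
    b_s: float = 0.50,
) -> float:
    t = (tmax + tmin) / 2.0
    es_tmax = 0.6108 * math.exp(17.27 * tmax / (tmax + 237.3))
    es_tmin = 0.6108 * math.exp(17.27 * tmin / (tmin + 237.3))
    es = (es_tmax + es_tmin) / 2.0
    ea = min(rh_mean / 100.0 * es, es)
    es_t = 0.6108 * math.exp(17.27 * t / (t + 237.3))
    delta = 4098.0 * es_t / (t + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * altitude_m) / 293.0) ** 5.26
    gamma = 0.665e-3 * pressure

    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi / 365.0 * doy)
    dec = 0.409 * math.sin(2.0 * math.pi / 365.0 * doy - 1.39)
    phi = math.radians(latitude_deg)
    ws = math.acos(-math.tan(phi) * math.tan(dec))
    ra = (
        24.0 * 60.0 / math.pi * 0.0820 * dr
        * (ws * math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.sin(ws))
    )
    n_max = 24.0 / math.pi * ws
    n = min(max(sunshine_hours, 0.0), n_max)
    rs = (a_s + b_s * n / n_max) * ra
    rso = (0.75 + 2e-5 * altitude_m) * ra
    rns = (1.0 - albedo) * rs
    rnl = (
        4.903e-9
        * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
        * (0.34 - 0.14 * math.sqrt(ea))
        * (1.35 * min(rs / rso, 1.0) - 0.35)
    )
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * 900.0 / (t + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(num / den, 0.0)
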