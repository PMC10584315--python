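"""Reference-evapotranspiration chain: worked values, physical bounds, and
agreement with an independent straight-line FAO-56 oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fao56_reference import reference_et0

from aquapot.weather import (
    PenmanTerms,
    SiteInfo,
    UnsupportedSiteError,
    attach_et0,
    daylight_hours,
    et0_penman_monteith,
    extraterrestrial_radiation,
    net_radiation,
    penman_terms_for_day,
    psychrometric_constant,
    read_weather_csv,
    saturation_vapour_pressure,
    slope_vapour_curve,
    write_weather_csv,
)


class TestVapourPressure:
    def test_worked_values(self):
        assert saturation_vapour_pressure(20.0) == pytest.approx(2.338, abs=5e-4)
        assert saturation_vapour_pressure(0.0) == pytest.approx(0.6108, abs=1e-12)

    def test_monotone(self):
        assert saturation_vapour_pressure(25.0) > saturation_vapour_pressure(20.0)

    def test_slope_worked_value(self):
        assert slope_vapour_curve(20.0) == pytest.approx(0.1447, abs=5e-4)

    def test_slope_convexity_and_finiteness(self):
        assert slope_vapour_curve(30.0) > slope_vapour_curve(20.0)
        assert np.isfinite(slope_vapour_curve(0.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=-39.9, max_value=60.0))
    def test_positive_on_domain(self, t):
        assert saturation_vapour_pressure(t) > 0
        assert slope_vapour_curve(t) > 0


class TestPsychrometricConstant:
    def test_site_altitude(self):
        assert psychrometric_constant(1489.0) == pytest.approx(0.0565, abs=2e-4)

    def test_sea_level(self):
        assert psychrometric_constant(0.0) == pytest.approx(0.0674, abs=2e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=-430.0, max_value=4000.0))
    def test_positive_and_decreasing(self, z):
        assert psychrometric_constant(z) > 0
        assert psychrometric_constant(2000.0) < psychrometric_constant(0.0)


class TestRadiation:
    def test_extraterrestrial_equinox_equator(self):
        # closed-form evaluation at the March equinox on the equator
        assert extraterrestrial_radiation(80, 0.0) == pytest.approx(37.824, abs=0.01)

    def test_polar_night_unsupported(self):
        with pytest.raises(UnsupportedSiteError):
            extraterrestrial_radiation(355, 80.0)

    def test_monotone_in_sunshine(self):
        base = dict(doy=180, latitude=36.8, altitude=1489.0, tmax=30.0,
                    tmin=15.0, ea=1.2)
        n = daylight_hours(180, 36.8)
        rn_low = net_radiation(sunshine_hours=0.3 * n, **base)
        rn_high = net_radiation(sunshine_hours=0.8 * n, **base)
        assert rn_high > rn_low

    def test_overcast_day_matches_reference_chain(self):
        """Rn with zero sunshine equals the independent inline evaluation of
        the same Angstrom + longwave chain."""
        import math
        doy, lat, alt = 150, 36.8, 1489.0
        tmax, tmin, ea = 25.0, 10.0, 1.0
        rn = net_radiation(doy, lat, alt, tmax, tmin, 0.0, ea)
        dr = 1 + 0.033 * math.cos(2 * math.pi * doy / 365)
        dec = 0.409 * math.sin(2 * math.pi * doy / 365 - 1.39)
        phi = math.radians(lat)
        ws = math.acos(-math.tan(phi) * math.tan(dec))
        ra = 24 * 60 / math.pi * 0.082 * dr * (
            ws * math.sin(phi) * math.sin(dec)
            + math.cos(phi) * math.cos(dec) * math.sin(ws)
        )
        rs = 0.25 * ra
        rso = (0.75 + 2e-5 * alt) * ra
        rnl = (
            4.903e-9 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2
            * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * rs / rso - 0.35)
        )
        assert rn == pytest.approx((1 - 0.23) * rs - rnl, abs=1e-12)


class TestPenmanMonteith:
    def test_worked_case(self):
        terms = PenmanTerms(rn=13.28, g=0.0, t_mean=20.0, u2=2.0,
                            es=2.0, ea=1.0, delta=0.145, gamma=0.066)
        assert et0_penman_monteith(terms) == pytest.approx(4.66, abs=1e-2)

    def test_no_energy_no_wind_gives_zero(self):
        terms = PenmanTerms(rn=5.0, g=5.0, t_mean=20.0, u2=0.0,
                            es=2.0, ea=1.0, delta=0.145, gamma=0.066)
        assert et0_penman_monteith(terms) == 0.0

    def test_wind_increases_demand_with_vapour_deficit(self):
        base = dict(rn=10.0, g=0.0, t_mean=20.0, es=2.0, ea=1.0,
                    delta=0.145, gamma=0.066)
        lo = et0_penman_monteith(PenmanTerms(u2=1.0, **base))
        hi = et0_penman_monteith(PenmanTerms(u2=3.0, **base))
        assert hi > lo

    def test_negative_balance_clamps_to_zero(self):
        terms = PenmanTerms(rn=-5.0, g=0.0, t_mean=0.0, u2=0.0,
                            es=0.6, ea=0.6, delta=0.045, gamma=0.066)
        assert et0_penman_monteith(terms) == 0.0


class TestAttachEt0:
    def test_idempotent(self, season_weather, site):
        again = attach_et0(season_weather, site)
        pd.testing.assert_series_equal(again["et0"], season_weather["et0"])

    def test_empty_series(self, site):
        empty = pd.DataFrame(columns=["date", "tmax", "tmin", "precip",
                                      "sunshine_hours", "rh_mean", "wind_u2"])
        out = attach_et0(empty, site)
        assert len(out) == 0 and "et0" in out.columns

    def test_physical_bounds_over_synthetic_year(self, season_weather):
        assert (season_weather["et0"] > 0).all()
        assert (season_weather["et0"] < 16).all()

    def test_missing_field_error_names_field_and_date(self, season_weather, site):
        broken = season_weather.drop(columns=["et0"]).copy()
        broken.loc[broken.index[3], "rh_mean"] = np.nan
        with pytest.raises(ValueError, match="rh_mean"):
            attach_et0(broken, site)

    def test_order_invariance(self, season_weather, site):
        shuffled = season_weather.drop(columns=["et0"]).sample(
            frac=1.0, random_state=0
        )
        out = attach_et0(shuffled, site).sort_values("date")
        expected = season_weather.sort_values("date")
        np.testing.assert_allclose(out["et0"].to_numpy(), expected["et0"].to_numpy())

    def test_csv_round_trip(self, season_weather, tmp_path):
        p = tmp_path / "wx.csv"
        write_weather_csv(season_weather, p)
        back = read_weather_csv(p)
        np.testing.assert_allclose(back["et0"], season_weather["et0"])
        assert (back["date"] == season_weather["date"]).all()


def test_et0_matches_independent_fao56_chain():
    """1000 random valid days agree with the straight-line reference
    implementation to 1e-9 mm/day."""
    rng = np.random.default_rng(123)
    site = SiteInfo(latitude=36.8, altitude=1489.0)
    for _ in range(1000):
        doy = int(rng.integers(1, 366))
        tmin = rng.uniform(-15, 25)
        tmax = tmin + rng.uniform(0.5, 20)
        rh = rng.uniform(10, 100)
        u2 = rng.uniform(0, 8)
        n_max = daylight_hours(doy, site.latitude)
        sun = rng.uniform(0, n_max)
        terms = penman_terms_for_day(
            pd.Timestamp("2020-01-01") + pd.Timedelta(days=doy - 1),
            tmax, tmin, sun, rh, u2, site,
        )
        got = et0_penman_monteith(terms)
        want = reference_et0(doy, site.latitude, site.altitude,
                             tmax, tmin, sun, rh, u2)
        assert got == pytest.approx(want, abs=1e-9)
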