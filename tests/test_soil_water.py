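"""Layered bucket balance: available water, stress coefficients, daily step
conservation, and root growth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquapot.soil import (
    SoilLayer,
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


class TestTotalAvailableWater:
    def test_measured_profile_at_max_root_depth(self, soil_profile):
        assert total_available_water(soil_profile, 0.45) == pytest.approx(43.5)

    def test_zero_root_depth(self, soil_profile):
        assert total_available_water(soil_profile, 0.0) == 0.0

    def test_deeper_roots_add_third_layer_water(self, soil_profile):
        # 43.5 mm at 0.45 m plus 0.11 * 50 mm for the next 5 cm of layer 3
        assert total_available_water(soil_profile, 0.50) == pytest.approx(49.0)
        assert total_available_water(soil_profile, 0.60) == pytest.approx(60.0)

    def test_increasing_in_root_depth(self, soil_profile):
        depths = np.linspace(0, 0.6, 13)
        taw = [total_available_water(soil_profile, d) for d in depths]
        assert all(b >= a for a, b in zip(taw, taw[1:]))

    def test_root_depth_beyond_profile_rejected(self, soil_profile):
        with pytest.raises(ValueError):
            total_available_water(soil_profile, 0.7)


class TestStressCoefficient:
    EXPANSION = StressThresholds(p_upper=0.26, p_lower=0.66)

    def test_no_stress_below_upper_threshold(self):
        assert stress_coefficient(0.20 * 43.5, 43.5, self.EXPANSION) == 1.0

    def test_full_stress_beyond_lower_threshold(self):
        assert stress_coefficient(0.80 * 43.5, 43.5, self.EXPANSION) == 0.0

    def test_linear_midpoint(self):
        assert stress_coefficient(0.46 * 43.5, 43.5, self.EXPANSION) == pytest.approx(0.5)

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            StressThresholds(p_upper=0.7, p_lower=0.6)

    def test_matches_brute_force_piecewise(self):
        """Agreement with an explicit piecewise evaluation on a 1000-point
        depletion grid, both shapes."""
        taw = 43.5
        for shape in ("linear", "convex"):
            thr = StressThresholds(p_upper=0.26, p_lower=0.66, shape=shape)
            for p in np.linspace(0, 1, 1000):
                got = stress_coefficient(p * taw, taw, thr)
                if p <= 0.26:
                    want = 1.0
                elif p >= 0.66:
                    want = 0.0
                else:
                    s = (p - 0.26) / 0.40
                    if shape == "linear":
                        want = 1.0 - s
                    else:
                        want = 1.0 - (np.expm1(3.0 * s) / np.expm1(3.0))
                assert got == pytest.approx(want, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=60), st.floats(min_value=0, max_value=60))
    def test_bounded_and_monotone(self, dr1, dr2):
        thr = self.EXPANSION
        k1 = stress_coefficient(dr1, 43.5, thr)
        k2 = stress_coefficient(dr2, 43.5, thr)
        assert 0.0 <= k1 <= 1.0
        if dr1 <= dr2:
            assert k1 >= k2


class TestSoilWaterStep:
    def test_no_fluxes_no_change(self, soil_profile):
        state = initial_state(soil_profile, 0.45)
        new, fluxes = soil_water_step(state, soil_profile)
        np.testing.assert_allclose(new.theta, state.theta)
        assert fluxes.drainage == 0.0

    def test_irrigation_on_full_profile_drains_through(self, soil_profile):
        state = initial_state(soil_profile, 0.45)
        before = storage_mm(state, soil_profile)
        new, fluxes = soil_water_step(state, soil_profile, irrigation=20.0)
        assert fluxes.drainage == pytest.approx(20.0)
        assert storage_mm(new, soil_profile) == pytest.approx(before)

    def test_transpiration_capped_by_available_water(self, soil_profile):
        # root zone holding 3 mm above wilting, 5 mm of rain, 10 mm demand
        state = initial_state(soil_profile, 0.20, condition=0.0)
        top = soil_profile.layers[0]
        state.theta[0] = top.theta_wp + 3.0 / top.thickness_mm
        before = storage_mm(state, soil_profile)
        new, fluxes = soil_water_step(state, soil_profile, rain=5.0, tr_demand=10.0)
        assert fluxes.tr_realized <= 8.0 + 1e-12
        delta = storage_mm(new, soil_profile) - before
        assert delta == pytest.approx(
            5.0 - fluxes.drainage - fluxes.e_realized - fluxes.tr_realized, abs=1e-9
        )

    def test_negative_flux_rejected(self, soil_profile):
        state = initial_state(soil_profile, 0.45)
        with pytest.raises(ValueError, match="rain"):
            soil_water_step(state, soil_profile, rain=-1.0)

    def test_season_closure_over_random_forcing(self, soil_profile):
        """Water balance closes to 1e-6 mm over 100 random synthetic seasons
        of 60 days each."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            state = initial_state(
                soil_profile, 0.45, condition=float(rng.uniform(0.1, 1.0))
            )
            start = storage_mm(state, soil_profile)
            inflow = outflow = 0.0
            for _day in range(60):
                rain = float(rng.exponential(2.0)) * (rng.random() < 0.3)
                irr = float(rng.choice([0.0, 10.0, 20.0]))
                e_d = float(rng.uniform(0, 6))
                tr_d = float(rng.uniform(0, 7))
                state, fx = soil_water_step(
                    state, soil_profile, rain=rain, irrigation=irr,
                    e_demand=e_d, tr_demand=tr_d,
                )
                inflow += rain + irr
                outflow += fx.drainage + fx.e_realized + fx.tr_realized
            end = storage_mm(state, soil_profile)
            assert abs((end - start) - (inflow - outflow)) < 1e-6

    def test_irrigation_never_increases_depletion(self, soil_profile):
        rng = np.random.default_rng(7)
        for _ in range(50):
            state = initial_state(
                soil_profile, 0.45, condition=float(rng.uniform(0.0, 1.0))
            )
            e_d, tr_d = float(rng.uniform(0, 6)), float(rng.uniform(0, 7))
            rain = float(rng.uniform(0, 5))
            dry, _ = soil_water_step(state.copy(), soil_profile, rain=rain,
                                     e_demand=e_d, tr_demand=tr_d)
            wet, _ = soil_water_step(state.copy(), soil_profile, rain=rain,
                                     irrigation=15.0, e_demand=e_d, tr_demand=tr_d)
            assert (
                root_zone_depletion(wet, soil_profile)
                <= root_zone_depletion(dry, soil_profile) + 1e-9
            )

    def test_air_dry_floor_respected(self, soil_profile):
        state = initial_state(soil_profile, 0.45, condition=0.0)
        for _ in range(30):
            state, _ = soil_water_step(state, soil_profile, e_demand=8.0, tr_demand=8.0)
        for theta, lay in zip(state.theta, soil_profile.layers):
            assert theta >= 0.5 * lay.theta_wp - 1e-12


class TestRootDepth:
    def test_starts_at_minimum(self):
        assert update_root_depth(0) == pytest.approx(0.20)

    def test_saturates_at_maximum(self):
        assert update_root_depth(75) == pytest.approx(0.45)
        assert update_root_depth(200) == pytest.approx(0.45)

    def test_linear_midpoint(self):
        mid = update_root_depth(37)
        assert mid == pytest.approx(0.20 + 0.25 * 37 / 75)
        assert 0.20 < mid < 0.45

    def test_non_decreasing(self):
        depths = [update_root_depth(d) for d in range(0, 160)]
        assert all(b >= a for a, b in zip(depths, depths[1:]))


class TestProfileValidation:
    def test_layer_ordering_enforced(self):
        with pytest.raises(ValueError):
            SoilLayer(0, 20, theta_wp=0.2, theta_fc=0.19, theta_sat=0.3)

    def test_non_contiguous_layers_rejected(self):
        l1 = SoilLayer(0, 20, 0.10, 0.19, 0.32)
        l3 = SoilLayer(40, 60, 0.12, 0.23, 0.38)
        with pytest.raises(ValueError, match="contiguous"):
            SoilProfile((l1, l3))
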