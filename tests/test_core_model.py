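import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomatopop.core_model import (ColorClock, FruitParams, GrowthParams,
                                  ModelInputError, gompertz_mass,
                                  hue_from_lab, mass_from_diameter,
                                  shift_time, simulate_fruit, switch_rate)


class TestMassFromDiameter:
    @pytest.mark.parametrize("diameter, expected", [
        (0.0, 0.0),
        (0.05, 0.0571377),  # 5 cm sphere at 873 kg/m^3
    ])
    def test_sphere_volume_formula(self, diameter, expected):
        assert mass_from_diameter(diameter) == pytest.approx(expected, rel=1e-5)

    def test_default_density_is_published_value(self):
        assert mass_from_diameter(0.05) == pytest.approx(
            mass_from_diameter(0.05, density=873.0))

    @pytest.mark.parametrize("diameter, density", [(-0.01, 873.0), (0.05, 0.0),
                                                   (0.05, -1.0)])
    def test_invalid_inputs_rejected(self, diameter, density):
        with pytest.raises(ModelInputError):
            mass_from_diameter(diameter, density)


class TestHueFromLab:
    @pytest.mark.parametrize("a, b, expected", [
        (10.0, 10.0, 45.0),       # symmetric red-yellow
        (20.0, 0.0, 0.0),         # pure red axis
        (-5.0, 20.0, 104.0362435),  # green fruit: a* < 0 maps above 90 deg
    ])
    def test_quadrant_corrected_angle(self, a, b, expected):
        assert hue_from_lab(a, b) == pytest.approx(expected, abs=1e-6)

    def test_undefined_at_origin(self):
        with pytest.raises(ModelInputError):
            hue_from_lab(0.0, 0.0)

    def test_green_fruit_above_ninety(self):
        assert hue_from_lab(-10.0, 15.0) > 90.0


class TestGompertzMass:
    def test_initial_condition(self):
        assert gompertz_mass(0.0, 107.1, 4.87, 0.0702) == pytest.approx(
            107.1 * np.exp(-4.87))

    def test_asymptote(self):
        assert gompertz_mass(1e6, 107.1, 4.87, 0.0702) == pytest.approx(107.1)

    def test_inflection_point(self):
        # at t = ln(C)/km the mass passes Mmax/e
        t_inf = np.log(4.87) / 0.0702
        assert t_inf == pytest.approx(22.56, abs=0.01)
        m = gompertz_mass(t_inf, 107.1, 4.87, 0.0702)
        assert m == pytest.approx(107.1 / np.e, rel=1e-12)
        assert m == pytest.approx(39.4, abs=0.05)


class TestSwitchRate:
    def test_rate_at_maximum_mass(self):
        assert switch_rate(107.1, 107.1, 26.02, 54.30) == pytest.approx(26.02)

    def test_rate_at_zero_mass(self):
        assert switch_rate(0.0, 107.1, 26.02, 54.30) == pytest.approx(
            26.02 * 2.0 ** -54.30)

    def test_near_ripe_rate(self):
        assert switch_rate(0.99 * 107.1, 107.1, 26.02, 54.30) == pytest.approx(
            15.2, abs=0.1)

    def test_monotone_and_continuous_in_mass(self):
        m = np.linspace(0.0, 107.1, 20000)
        kh = switch_rate(m, 107.1, 26.02, 54.30)
        assert np.all(np.diff(kh) > 0)
        # steepest slope is kh_max*s/Mmax at M = Mmax; no jumps beyond it
        step = m[1] - m[0]
        assert np.max(np.diff(kh)) < 1.05 * 26.02 * 54.30 / 107.1 * step

    def test_overweight_fruit_rejected(self):
        with pytest.raises(ModelInputError):
            switch_rate(108.0, 107.1, 26.02, 54.30)


def test_shift_time_examples():
    assert shift_time(10.0, 7.01) == pytest.approx(17.01)
    assert shift_time(3.5, 0.0) == 3.5
    assert shift_time(-7.01, 7.01) == pytest.approx(0.0)


class TestSimulateFruit:
    def test_mass_matches_closed_form(self, winter_growth):
        fruit = FruitParams(Mmax=107.1, delta_t=0.0)
        t = np.linspace(0.0, 80.0, 161)
        traj = simulate_fruit(winter_growth, fruit, t)
        oracle = gompertz_mass(t, fruit.Mmax, winter_growth.C, winter_growth.km)
        assert np.max(np.abs(traj.mass - oracle)) < 1e-6 * fruit.Mmax

    def test_trajectory_invariants(self, winter_growth):
        fruit = FruitParams(Mmax=80.0, delta_t=0.0)
        t = np.linspace(0.0, 90.0, 181)
        traj = simulate_fruit(winter_growth, fruit, t)
        traj.validate(winter_growth, fruit)

    def test_zero_color_rate_keeps_initial_hue(self, winter_growth):
        g = winter_growth.replace(kh_max=0.0)
        traj = simulate_fruit(g, FruitParams(Mmax=100.0, delta_t=0.0),
                              np.linspace(0.0, 80.0, 81))
        assert np.allclose(traj.hue, g.H0, atol=1e-9)

    def test_hue_reaches_minimum(self, winter_growth):
        traj = simulate_fruit(winter_growth, FruitParams(Mmax=100.0, delta_t=0.0),
                              np.linspace(0.0, 120.0, 121))
        assert traj.hue[-1] == pytest.approx(winter_growth.Hmin, abs=1e-3)

    def test_time_translation_covariance(self, winter_growth):
        # replacing C by C*exp(km*delta) and shifting the grid reproduces the
        # trajectory: the gauge degeneracy constrained during calibration
        delta = 5.0
        fruit = FruitParams(Mmax=100.0, delta_t=0.0)
        t = np.linspace(10.0, 80.0, 71)
        ref = simulate_fruit(winter_growth, fruit, t)
        g2 = winter_growth.replace(C=winter_growth.C * np.exp(winter_growth.km * delta))
        shifted = simulate_fruit(g2, fruit, t + delta)
        assert np.allclose(shifted.mass, ref.mass, rtol=1e-6)
        assert np.allclose(shifted.hue, ref.hue, atol=1e-4)

    def test_bad_grid_rejected(self, winter_growth):
        fruit = FruitParams(Mmax=100.0, delta_t=0.0)
        with pytest.raises(ModelInputError):
            simulate_fruit(winter_growth, fruit, [-1.0, 0.0, 1.0])
        with pytest.raises(ModelInputError):
            simulate_fruit(winter_growth, fruit, [0.0, 0.0, 1.0])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    C=st.floats(1.0, 10.0), km=st.floats(0.03, 0.2),
    kh_max=st.floats(0.5, 30.0), H0=st.floats(90.0, 120.0),
    Hmin=st.floats(40.0, 60.0), s=st.floats(5.0, 80.0),
    Mmax=st.floats(20.0, 300.0),
)
def test_oracle_equivalence_and_hue_bounds(C, km, kh_max, H0, Hmin, s, Mmax):
    """Numeric solution equals the Gompertz closed form and the hue stays
    monotone within [Hmin, H0] across admissible parameters."""
    g = GrowthParams(C=C, km=km, kh_max=kh_max, H0=H0, Hmin=Hmin, s=s)
    t = np.linspace(0.0, 1.2 * np.log(C / 1e-3) / km, 120)
    traj = simulate_fruit(g, FruitParams(Mmax=Mmax, delta_t=0.0), t)
    oracle = gompertz_mass(t, Mmax, C, km)
    assert np.max(np.abs(traj.mass - oracle)) < 1e-6 * Mmax
    assert np.all(np.diff(traj.hue) <= 1e-9)
    assert np.all(traj.hue <= H0 + 1e-7)
    assert np.all(traj.hue >= Hmin - 1e-7)


def test_color_clock_matches_ode(winter_growth):
    """The quadrature-based hue solution agrees with the ODE integration."""
    t = np.linspace(0.0, 100.0, 201)
    traj = simulate_fruit(winter_growth, FruitParams(Mmax=107.1, delta_t=0.0), t)
    clock = ColorClock(winter_growth, 0.0, 100.0)
    assert np.max(np.abs(clock.hue(t) - traj.hue)) < 1e-3

    # monotone inversion round-trips
    age = clock.age_at_hue(80.0)
    assert clock.hue(age) == pytest.approx(80.0, abs=1e-6)


def test_growth_params_invariants_enforced():
    with pytest.raises(ModelInputError):
        GrowthParams(C=-1.0, km=0.07, kh_max=26.0, H0=105.0, Hmin=52.0, s=54.0)
    with pytest.raises(ModelInputError):
        GrowthParams(C=4.87, km=0.07, kh_max=26.0, H0=50.0, Hmin=52.0, s=54.0)
    with pytest.raises(ModelInputError):
        FruitParams(Mmax=-5.0, delta_t=0.0)
    with pytest.raises(ModelInputError):
        FruitParams(Mmax=100.0, delta_t=float("nan"))
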