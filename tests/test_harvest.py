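import numpy as np
import pytest

from tomatopop.core_model import ModelInputError, simulate_fruit
from tomatopop.datasets import WINTER_GROWTH
from tomatopop.harvest import (HarvestStrategy, apply_harvest_strategy,
                               compare_strategies, event_breakdown,
                               single_harvest_sweep)
from tomatopop.population import (PopulationSample, RipeningStageScheme,
                                  simulate_population)
from tomatopop.price_model import predict_price


def _mass_accounted(traj, outcome):
    """Independent conservation oracle: every fruit's mass at the date it was
    removed (harvested or wasted), or at window end if never removed."""
    removal_date = np.full(traj.n, outcome.strategy.window_end)
    removed = np.zeros(traj.n, dtype=bool)
    total_event_mass = 0.0
    for e in outcome.events:
        newly = np.zeros(traj.n, dtype=bool)
        newly[e.harvested_ids] = True
        newly[e.waste_ids] = True
        assert not np.any(newly & removed), "fruit removed twice"
        removal_date[newly] = e.date
        removed |= newly
        total_event_mass += e.saleable_mass + e.waste_mass
    per_fruit = 0.0
    for i in range(traj.n):
        mass, _ = traj.state_at(float(removal_date[i]))
        per_fruit += mass[i]
    return per_fruit, total_event_mass


class TestStrategyValidation:
    def test_modes_and_required_fields(self):
        with pytest.raises(ModelInputError):
            HarvestStrategy(mode="weekly", window_start=0, window_end=10)
        with pytest.raises(ModelInputError):
            HarvestStrategy(mode="single", window_start=0, window_end=10)
        with pytest.raises(ModelInputError):
            HarvestStrategy(mode="fixed_interval", interval=0.5,
                            window_start=0, window_end=10)
        with pytest.raises(ModelInputError):
            HarvestStrategy(mode="dynamic", schedule=(5.0, 3.0),
                            window_start=0, window_end=10)
        with pytest.raises(ModelInputError):
            HarvestStrategy(mode="dynamic", schedule=(5.0, 12.0),
                            window_start=0, window_end=10)

    def test_fixed_interval_dates(self):
        s = HarvestStrategy(mode="fixed_interval", interval=3.0,
                            window_start=40.0, window_end=50.0)
        assert np.allclose(s.dates(), [40.0, 43.0, 46.0, 49.0])

    def test_round_trip(self):
        s = HarvestStrategy(mode="dynamic", schedule=(42.0, 46.0, 49.0),
                            target_stages=("RS5", "RS6"),
                            window_start=40.0, window_end=70.0)
        assert HarvestStrategy.from_dict(s.to_dict()) == s


class TestApplyHarvestStrategy:
    def test_mass_conservation(self, small_population, winter_coeffs):
        traj = small_population
        strategies = [
            HarvestStrategy(mode="single", schedule=(50.0,),
                            window_start=40.0, window_end=70.0),
            HarvestStrategy(mode="fixed_interval", interval=2.0,
                            target_stages=("RS5", "RS6"),
                            window_start=40.0, window_end=70.0),
            HarvestStrategy(mode="dynamic", schedule=(44.0, 49.0, 53.0, 56.0),
                            target_stages=("RS4", "RS5", "RS6"),
                            window_start=40.0, window_end=70.0),
        ]
        for strat in strategies:
            out = apply_harvest_strategy(traj, strat, coeffs=winter_coeffs)
            removed = out.total_saleable_mass + out.total_waste_mass
            per_fruit, event_mass = _mass_accounted(traj, out)
            assert event_mass == pytest.approx(removed, rel=1e-9)
            total = removed + out.unharvested_mass
            assert total == pytest.approx(per_fruit, rel=1e-9)
            assert out.cumulative_value == pytest.approx(
                sum(e.value for e in out.events), rel=1e-12)

    def test_single_harvest_after_full_ripening_is_all_waste(
            self, small_population, winter_coeffs):
        strat = HarvestStrategy(mode="single", schedule=(88.0,),
                                window_start=40.0, window_end=89.0)
        out = apply_harvest_strategy(small_population, strat,
                                     coeffs=winter_coeffs)
        assert out.cumulative_value == 0.0
        assert out.total_saleable_mass == 0.0
        assert out.total_waste_mass > 0.0
        assert out.unharvested_ids.size == 0

    def test_unreachable_targets_leave_crop_unharvested(
            self, small_population, winter_coeffs):
        # everything is still green early in the window
        strat = HarvestStrategy(mode="fixed_interval", interval=2.0,
                                target_stages=("RS6",),
                                window_start=1.0, window_end=15.0)
        out = apply_harvest_strategy(small_population, strat,
                                     coeffs=winter_coeffs)
        assert out.cumulative_value == 0.0
        assert out.unharvested_ids.size == small_population.n
        assert all(e.value == 0.0 for e in out.events)

    def test_two_fruit_event_reproduces_hand_computation(self, winter_coeffs):
        """Single harvest between two fruits' colour breaks: composition and
        value recomputed from independent per-fruit ODE trajectories."""
        pop = PopulationSample(mmax=np.array([90.0, 120.0]),
                               delta_t=np.array([10.0, 0.0]), seed=0)
        t_grid = np.linspace(0.0, 75.0, 151)
        traj = simulate_population(WINTER_GROWTH, pop, t_grid)
        date = 50.0
        strat = HarvestStrategy(mode="single", schedule=(date,),
                                window_start=45.0, window_end=70.0)
        out = apply_harvest_strategy(traj, strat, coeffs=winter_coeffs)
        # independent route: two-state ODE solutions per fruit
        scheme = RipeningStageScheme()
        masses, hues = [], []
        for i in range(2):
            ref = simulate_fruit(WINTER_GROWTH, pop.fruit_params(i),
                                 np.array([1.0, date]) + pop.delta_t[i])
            masses.append(ref.mass[-1])
            hues.append(ref.hue[-1])
        # fruit 0 (shift 10 d) is ripening; fruit 1 is still green
        assert hues[0] < 75.0 < 95.0 < hues[1]
        from tomatopop.population import stage_codes
        codes = [int(stage_codes(h, scheme)) for h in hues]
        assert all(c < 6 for c in codes)  # neither fruit is waste yet
        comp = np.zeros(6)
        for m, c in zip(masses, codes):
            comp[c] += m
        comp /= sum(masses)
        ev = out.events[0]
        assert ev.saleable_mass == pytest.approx(sum(masses), rel=1e-4)
        assert np.allclose(ev.composition, comp, atol=1e-4)
        assert ev.value == pytest.approx(
            predict_price(winter_coeffs, comp[None, :]) * sum(masses) / 1000.0,
            rel=1e-3)

    def test_dense_all_stage_harvest_leaves_no_waste(
            self, small_population, winter_coeffs):
        strat = HarvestStrategy(mode="fixed_interval", interval=1.0,
                                target_stages=("RS1", "RS2", "RS3", "RS4",
                                               "RS5", "RS6"),
                                window_start=1.0, window_end=89.0)
        out = apply_harvest_strategy(small_population, strat,
                                     coeffs=winter_coeffs)
        assert out.total_waste_mass == 0.0
        assert out.unharvested_ids.size == 0

    def test_schedule_outside_grid_rejected(self, small_population,
                                            winter_coeffs):
        strat = HarvestStrategy(mode="single", schedule=(200.0,),
                                window_start=100.0, window_end=201.0)
        with pytest.raises(ModelInputError):
            apply_harvest_strategy(small_population, strat,
                                   coeffs=winter_coeffs)


class TestSingleHarvestSweep:
    def test_waste_monotone_and_terminal_zero(self, small_population,
                                              winter_coeffs):
        sweep = single_harvest_sweep(small_population, (40.0, 88.0),
                                     coeffs=winter_coeffs)
        waste = sweep["waste_mass_g"].to_numpy()
        assert np.all(np.diff(waste) >= -1e-9)
        assert sweep["value"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_value_peaks_after_saleable_mass(self, small_population,
                                             winter_coeffs):
        sweep = single_harvest_sweep(small_population, (40.0, 88.0),
                                     coeffs=winter_coeffs)
        mass_peak = sweep.loc[sweep["saleable_mass_g"].idxmax(), "date"]
        assert sweep.attrs["optimal_date"] > mass_peak


class TestCompareStrategies:
    def test_duplicate_strategies_identical(self, small_population,
                                            winter_coeffs):
        a = HarvestStrategy(mode="fixed_interval", interval=2.0,
                            target_stages=("RS5", "RS6"), name="a",
                            window_start=40.0, window_end=70.0)
        b = HarvestStrategy(mode="fixed_interval", interval=2.0,
                            target_stages=("RS5", "RS6"), name="b",
                            window_start=40.0, window_end=70.0)
        table, outcomes = compare_strategies(small_population, [a, b],
                                             coeffs=winter_coeffs)
        cols = ["cumulative_value", "saleable_mass_g", "waste_mass_g",
                "n_harvests"]
        assert table.loc[0, cols].tolist() == table.loc[1, cols].tolist()
        bd = event_breakdown(outcomes)
        assert (bd[bd.strategy == "a"]["value"].to_numpy() ==
                bd[bd.strategy == "b"]["value"].to_numpy()).all()

    def test_relative_value_normalized_to_best(self, small_population,
                                               winter_coeffs):
        strategies = [
            HarvestStrategy(mode="fixed_interval", interval=i,
                            target_stages=("RS5", "RS6"),
                            window_start=40.0, window_end=70.0)
            for i in (1.0, 3.0)
        ]
        table, _ = compare_strategies(small_population, strategies,
                                      coeffs=winter_coeffs)
        assert table["relative_value"].iloc[0] == pytest.approx(1.0)
        assert (table["relative_value"] <= 1.0 + 1e-12).all()
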