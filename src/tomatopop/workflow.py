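"""High-level pipeline helpers tying population, price and harvest together."""

from __future__ import annotations

import numpy as np

from .core_model import ColorClock
from .datasets import POPULATION_MOMENTS, growth_params
from .harvest import HarvestStrategy, compare_strategies, single_harvest_sweep
from .population import (PopulationDistribution, RipeningStageScheme,
                         sample_population, simulate_population)
from .price_model import PriceCoefficients

__all__ = [
    "published_distribution",
    "simulate_study_population",
    "first_rs6_date",
    "standard_strategy_set",
    "standard_comparison",
]

#: Harvest window length (d) considered around crop ripening.
HARVEST_WINDOW_D = 30.0
#: Default dynamic-harvest dates as offsets (d) from the window start:
#: sparse while the crop ripens slowly, tighter once ripening accelerates.
DYNAMIC_OFFSETS = (4.0, 9.0, 13.0, 16.0, 19.0, 22.0)


def published_distribution(season: str) -> PopulationDistribution:
    """Per-fruit parameter distribution at the published seasonal moments."""
    m = POPULATION_MOMENTS[season]
    return PopulationDistribution(
        mmax_mean=m["Mmax"][0], mmax_sd=m["Mmax"][1],
        dt_mean=m["delta_t"][0], dt_sd=m["delta_t"][1],
    )


def simulate_study_population(season: str, seed: int, n_fruit: int = 10000,
                              t_max: float | None = None, t_step: float = 0.5):
    """Sample and simulate a virtual crop under the published season conditions."""
    growth = growth_params(season)
    dist = published_distribution(season)
    pop = sample_population(dist, n_fruit, seed)
    if t_max is None:
        # run until the oldest fruit is well past full ripeness
        clock = ColorClock(growth, 0.0, 4.0 * np.log(growth.C / 1e-4) / growth.km,
                           step=0.02)
        a_end = clock.age_at_hue(growth.Hmin + 0.2)
        t_max = float(np.ceil(a_end - pop.delta_t.min() + 2.0))
    t_grid = np.arange(0.0, t_max + 1e-9, t_step)
    return simulate_population(growth, pop, t_grid)


def first_rs6_date(traj, scheme: RipeningStageScheme | None = None) -> float:
    """First observation-clock date at which any fruit reaches RS6."""
    scheme = scheme or RipeningStageScheme()
    clock = traj._clock
    a_rs6 = clock.age_at_hue(scheme.lower_bounds[4])  # RS6 upper edge
    return float(a_rs6 - traj.sample.delta_t.max())


def standard_strategy_set(window_start: float, window_end: float,
                          single_date: float) -> list:
    """The standard comparison: one single harvest, fixed 1-4 d intervals for
    the RS5-RS6 and RS4-RS6 maturity ranges, and one dynamic schedule."""
    strategies = [HarvestStrategy(mode="single", window_start=window_start,
                                  window_end=window_end, schedule=(single_date,))]
    for stages in (("RS5", "RS6"), ("RS4", "RS5", "RS6")):
        for interval in (1, 2, 3, 4):
            strategies.append(HarvestStrategy(
                mode="fixed_interval", interval=float(interval),
                target_stages=stages, window_start=window_start,
                window_end=window_end))
    schedule = tuple(window_start + o for o in DYNAMIC_OFFSETS
                     if window_start + o <= window_end)
    strategies.append(HarvestStrategy(
        mode="dynamic", schedule=schedule, target_stages=("RS5", "RS6"),
        window_start=window_start, window_end=window_end))
    return strategies


def standard_comparison(season: str = "winter", seed: int = 0,
                        n_fruit: int = 10000, strategies=None,
                        scheme: RipeningStageScheme | None = None,
                        coeffs: PriceCoefficients | None = None):
    """Simulate a crop and rank the standard (or supplied) strategies.

    Returns ``(table, outcomes, sweep)`` where the sweep is the single-harvest
    value/mass/waste series over the harvest window.
    """
    scheme = scheme or RipeningStageScheme()
    coeffs = coeffs or PriceCoefficients.from_published(season)
    traj = simulate_study_population(season, seed, n_fruit)
    start = max(first_rs6_date(traj, scheme), float(traj.t_grid[0]))
    end = start + HARVEST_WINDOW_D
    if end > traj.t_grid[-1]:
        traj = simulate_study_population(season, seed, n_fruit,
                                         t_max=float(np.ceil(end + 1.0)))
    sweep = single_harvest_sweep(traj, (start, end), scheme=scheme, coeffs=coeffs)
    if strategies is None:
        strategies = standard_strategy_set(start, end, sweep.attrs["optimal_date"])
    table, outcomes = compare_strategies(traj, strategies, scheme=scheme,
                                         coeffs=coeffs)
    return table, outcomes, sweep
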