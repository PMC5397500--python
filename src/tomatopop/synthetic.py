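"""Synthetic field cohorts and wholesaler price surveys.

The study conditions are emulated end to end: a seasonal cohort of a few
hundred labeled fruit, each with its own final mass and biological-age shift,
monitored on the plant every 3 d during growth and every 2 d during ripening
with independent Gaussian measurement noise on mass and hue; and a panel of
raters pricing the 13-mixture survey design, with per-rater noise followed by
per-rater min-max normalization.  Generators are pure functions of
(spec, seed) and return the generating truth for recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ObservationSeries
from .core_model import ColorClock, GrowthParams, ModelInputError, gompertz_mass
from .datasets import POPULATION_MOMENTS, growth_params, mixture_design
from .population import PopulationDistribution, sample_population
from .price_model import PriceCoefficients, build_design_matrix, normalize_prices

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticSurveySpec",
    "gen_fruit_observations",
    "gen_price_survey",
    "winter_cohort_spec",
    "summer_cohort_spec",
]

#: Hue drop below the initial hue that marks the onset of the denser
#: ripening-phase sampling cadence.
RIPENING_ONSET_DROP = 2.0
#: Monitoring stops once the fruit is this far (deg) above the waste edge.
MONITOR_MARGIN = 2.0


@dataclass
class SyntheticCohortSpec:
    """Blueprint of one seasonal observation campaign."""

    n_fruit: int
    growth: GrowthParams
    population: PopulationDistribution
    seed: int = 0
    season: str = ""
    n_cohorts: int = 3  # flowering-label rounds (metadata)
    cohort_spacing: float = 5.0  # d between label rounds (metadata)
    growth_interval: float = 3.0  # d between observations before colour break
    ripening_interval: float = 2.0  # d between observations during ripening
    mass_noise_sd: float = 2.0  # g
    hue_noise_sd: float = 1.0  # degrees
    waste_hue: float = 54.0  # monitoring runs until hue < waste_hue + margin

    def __post_init__(self) -> None:
        if self.n_fruit <= 0 or self.n_cohorts <= 0:
            raise ModelInputError("counts must be positive")
        if self.growth_interval <= 0 or self.ripening_interval <= 0 \
                or self.cohort_spacing <= 0:
            raise ModelInputError("intervals must be positive")
        if self.mass_noise_sd < 0 or self.hue_noise_sd < 0:
            raise ModelInputError("noise sds must be non-negative")


def winter_cohort_spec(seed: int = 0, n_fruit: int | None = None) -> SyntheticCohortSpec:
    """Winter study conditions: 342 fruit, published winter parameters."""
    m = POPULATION_MOMENTS["winter"]
    dist = PopulationDistribution(mmax_mean=m["Mmax"][0], mmax_sd=m["Mmax"][1],
                                  dt_mean=m["delta_t"][0], dt_sd=m["delta_t"][1])
    return SyntheticCohortSpec(n_fruit=n_fruit or 342, growth=growth_params("winter"),
                               population=dist, seed=seed, season="winter")


def summer_cohort_spec(seed: int = 0, n_fruit: int | None = None) -> SyntheticCohortSpec:
    """Summer study conditions: 370 fruit, published summer parameters."""
    m = POPULATION_MOMENTS["summer"]
    dist = PopulationDistribution(mmax_mean=m["Mmax"][0], mmax_sd=m["Mmax"][1],
                                  dt_mean=m["delta_t"][0], dt_sd=m["delta_t"][1])
    return SyntheticCohortSpec(n_fruit=n_fruit or 370, growth=growth_params("summer"),
                               population=dist, seed=seed, season="summer")


def _observation_times(t_break: float, t_end: float, growth_iv: float,
                       ripening_iv: float) -> np.ndarray:
    """Sampling dates: growth cadence until the colour break, ripening cadence
    until just past full ripeness.  Guarantees at least 4 observations."""
    t_break = max(t_break, 0.0)
    growth_times = np.arange(0.0, t_break, growth_iv)
    start = growth_times[-1] + ripening_iv if growth_times.size else 0.0
    ripening_times = np.arange(start, max(t_end, start) + ripening_iv, ripening_iv)
    times = np.concatenate([growth_times, ripening_times])
    while times.size < 4:  # pragma: no cover - extreme shifts only
        times = np.append(times, times[-1] + ripening_iv)
    return times


def gen_fruit_observations(spec: SyntheticCohortSpec):
    """Generate a cohort of noisy per-fruit observation series.

    Returns ``(series, truth)`` where truth holds the generating growth
    parameters and the per-fruit (Mmax, delta_t) arrays.
    """
    rng = np.random.default_rng(spec.seed)
    pop = sample_population(spec.population, spec.n_fruit, spec.seed)
    g = spec.growth

    # shared hue-age profile: invert once for the cadence switch and the end
    # of monitoring (both are Mmax-free)
    span = 2.0 * np.log(g.C / 1e-4) / g.km  # generous age span; hue long ripe by then
    clock = ColorClock(g, min(0.0, float(pop.delta_t.min())) - 1.0,
                       span + float(pop.delta_t.max()), step=0.01)
    a_break = clock.age_at_hue(g.H0 - RIPENING_ONSET_DROP)
    a_end = clock.age_at_hue(max(spec.waste_hue + MONITOR_MARGIN, g.Hmin + 0.5))

    series = []
    cohort_of = np.arange(spec.n_fruit) % spec.n_cohorts
    for i in range(spec.n_fruit):
        dt = float(pop.delta_t[i])
        times = _observation_times(a_break - dt, a_end - dt,
                                   spec.growth_interval, spec.ripening_interval)
        ages = times + dt
        mass = gompertz_mass(ages, float(pop.mmax[i]), g.C, g.km)
        hue = clock.hue(ages)
        if spec.mass_noise_sd > 0:
            mass = mass + rng.normal(0.0, spec.mass_noise_sd, mass.shape)
        if spec.hue_noise_sd > 0:
            hue = hue + rng.normal(0.0, spec.hue_noise_sd, hue.shape)
        hue = np.clip(hue, 1e-6, 180.0)
        series.append(ObservationSeries(
            fruit_id=f"{spec.season or 'fruit'}_{i:04d}",
            t_exp=times, mass_obs=mass, hue_obs=hue, season=spec.season,
        ))
    truth = {
        "growth": g, "mmax": pop.mmax.copy(), "delta_t": pop.delta_t.copy(),
        "cohort": cohort_of, "seed": spec.seed,
    }
    return series, truth


@dataclass
class SyntheticSurveySpec:
    """Blueprint of a wholesaler pricing survey."""

    n_raters: int = 30
    coefficients: PriceCoefficients | None = None  # defaults to published winter
    design: pd.DataFrame | None = None  # defaults to the 13-mixture design
    noise_sd: float = 0.1
    season: str = "winter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ModelInputError("need at least one rater")
        if self.noise_sd < 0:
            raise ModelInputError("noise sd must be non-negative")
        if self.coefficients is None:
            self.coefficients = PriceCoefficients.from_published(self.season)
        if self.design is None:
            self.design = mixture_design()
        build_design_matrix(self.design)  # validates compositions


def gen_price_survey(spec: SyntheticSurveySpec):
    """Generate a rater x mixture price survey.

    Per rater, raw prices are the mixture-model evaluation plus iid Gaussian
    rater noise, then min-max normalized within the rater.  Returns
    ``(survey, truth)``; the survey DataFrame has one row per rater per
    mixture with rs1..rs6, raw_price and normalized_price columns.
    """
    rng = np.random.default_rng(spec.seed)
    X = build_design_matrix(spec.design).to_numpy()
    base = X @ spec.coefficients.alphas
    frames = []
    for r in range(spec.n_raters):
        noise = rng.normal(0.0, spec.noise_sd, base.shape) if spec.noise_sd > 0 else 0.0
        df = pd.DataFrame(spec.design.to_numpy(dtype=float),
                          columns=list(spec.design.columns))
        df.insert(0, "rater_id", f"rater_{r:02d}")
        df.insert(1, "season", spec.season)
        df["raw_price"] = base + noise
        frames.append(df)
    survey = pd.concat(frames, ignore_index=True)
    survey = normalize_prices(survey)
    truth = {"coefficients": spec.coefficients, "noiseless_prices": base,
             "seed": spec.seed}
    return survey, truth
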