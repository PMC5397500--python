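import numpy as np
import pytest

from tomatopop.calibration import CalibrationConfig, calibrate
from tomatopop.datasets import WINTER_GROWTH
from tomatopop.population import (PopulationDistribution, sample_population,
                                  simulate_population)
from tomatopop.price_model import PriceCoefficients
from tomatopop.synthetic import gen_fruit_observations, winter_cohort_spec


@pytest.fixture(scope="session")
def winter_growth():
    return WINTER_GROWTH


@pytest.fixture(scope="session")
def winter_coeffs():
    return PriceCoefficients.from_published("winter")


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 60-fruit winter-like cohort with its generating truth."""
    spec = winter_cohort_spec(seed=7, n_fruit=60)
    return gen_fruit_observations(spec)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Exact (noise-free) 20-fruit cohort for self-consistency oracles."""
    spec = winter_cohort_spec(seed=5, n_fruit=20)
    spec.mass_noise_sd = 0.0
    spec.hue_noise_sd = 0.0
    return gen_fruit_observations(spec)


@pytest.fixture(scope="session")
def small_cohort_fit(small_cohort):
    """Joint calibration of the small cohort, gauge fixed at generating C."""
    series, truth = small_cohort
    return calibrate(series, CalibrationConfig(fix={"C": truth["growth"].C}))


@pytest.fixture(scope="session")
def small_population():
    """200 virtual winter fruit simulated over the full ripening horizon."""
    dist = PopulationDistribution(mmax_mean=107.1, mmax_sd=36.9,
                                  dt_mean=7.01, dt_sd=2.82)
    pop = sample_population(dist, 200, seed=13)
    t_grid = np.arange(0.0, 90.0 + 1e-9, 0.5)
    return simulate_population(WINTER_GROWTH, pop, t_grid)
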