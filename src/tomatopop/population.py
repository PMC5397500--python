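"""Monte Carlo fruit populations and ripening-stage accounting.

A virtual crop is a sample of per-fruit parameters (Mmax, delta_t) drawn from
a distribution fitted to the calibrated fruit, preserving the mean, spread,
shape and correlation of the estimates.  Simulating the kinetic model for
every virtual fruit on a shared observation clock yields time-varying
population distributions of mass and hue, which are discretized into the six
commercial ripening stages (RS1 mature green ... RS6 red ripe) plus an
overripe WASTE class below the waste hue threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_model import ColorClock, FruitParams, GrowthParams, ModelInputError

__all__ = [
    "STAGE_LABELS",
    "WASTE",
    "PopulationDistribution",
    "PopulationSample",
    "RipeningStageScheme",
    "PopulationTrajectories",
    "fit_population_distribution",
    "sample_population",
    "simulate_population",
    "classify_stage",
    "stage_tally",
]

STAGE_LABELS = ("RS1", "RS2", "RS3", "RS4", "RS5", "RS6")
WASTE = "WASTE"


@dataclass(frozen=True)
class PopulationDistribution:
    """Joint distribution of per-fruit (Mmax, delta_t).

    Marginals are parameterized by their (location, scale) moments; Mmax uses
    either a zero-truncated normal (default) or a lognormal matched to the
    same mean/sd, delta_t is normal.  Dependence is a Gaussian copula with
    the given correlation (default independent).
    """

    mmax_mean: float
    mmax_sd: float
    dt_mean: float
    dt_sd: float
    correlation: float = 0.0
    mmax_family: str = "truncnorm"
    provenance: str = "specified"

    def __post_init__(self) -> None:
        if self.mmax_mean <= 0 or self.mmax_sd <= 0 or self.dt_sd <= 0:
            raise ModelInputError("marginal moments must be positive")
        if not -1.0 <= self.correlation <= 1.0:
            raise ModelInputError("correlation must lie in [-1, 1]")
        if self.mmax_family not in ("truncnorm", "lognormal"):
            raise ModelInputError(f"unknown Mmax family {self.mmax_family!r}")

    def to_dict(self) -> dict:
        return {
            "mmax_mean": self.mmax_mean, "mmax_sd": self.mmax_sd,
            "dt_mean": self.dt_mean, "dt_sd": self.dt_sd,
            "correlation": self.correlation, "mmax_family": self.mmax_family,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationDistribution":
        return cls(**d)

    def _mmax_marginal(self):
        if self.mmax_family == "truncnorm":
            a = (0.0 - self.mmax_mean) / self.mmax_sd
            return stats.truncnorm(a, np.inf, loc=self.mmax_mean, scale=self.mmax_sd)
        # lognormal matched to the stated mean/sd (captures the right skew
        # seen in the fitted Mmax histograms)
        cv2 = (self.mmax_sd / self.mmax_mean) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(self.mmax_mean) - sigma**2 / 2
        return stats.lognorm(sigma, scale=np.exp(mu))


@dataclass
class PopulationSample:
    """N virtual fruits' parameters plus the seed that produced them."""

    mmax: np.ndarray  # g
    delta_t: np.ndarray  # d
    seed: int

    def __post_init__(self) -> None:
        self.mmax = np.asarray(self.mmax, dtype=float)
        self.delta_t = np.asarray(self.delta_t, dtype=float)
        if self.mmax.size == 0 or self.mmax.shape != self.delta_t.shape:
            raise ModelInputError("sample must be non-empty with matching shapes")
        if np.any(self.mmax <= 0):
            raise ModelInputError("all Mmax must be positive")

    @property
    def n(self) -> int:
        return self.mmax.size

    def fruit_params(self, i: int) -> FruitParams:
        return FruitParams(Mmax=float(self.mmax[i]), delta_t=float(self.delta_t[i]))


@dataclass(frozen=True)
class RipeningStageScheme:
    """Hue boundaries of the commercial ripening stages.

    ``lower_bounds[k]`` is the (inclusive) lower hue edge of stage RS(k+1);
    below the last edge the fruit is overripe WASTE.  Only the 54 deg waste
    edge is an established value; the intermediate defaults are configurable
    working values.  Convention: intervals are half-open with the lower bound
    included, so a fruit exactly on an edge belongs to the stage whose lower
    edge it is.
    """

    lower_bounds: tuple = (95.0, 85.0, 75.0, 65.0, 58.0, 54.0)

    def __post_init__(self) -> None:
        lb = tuple(float(x) for x in self.lower_bounds)
        if len(lb) != 6 or any(a >= b for a, b in zip(lb[1:], lb[:-1])):
            raise ModelInputError("need 6 strictly decreasing stage lower bounds")
        object.__setattr__(self, "lower_bounds", lb)

    @property
    def waste_threshold(self) -> float:
        return self.lower_bounds[-1]

    def to_dict(self) -> dict:
        return {"lower_bounds": list(self.lower_bounds)}

    @classmethod
    def from_dict(cls, d: dict) -> "RipeningStageScheme":
        return cls(lower_bounds=tuple(d["lower_bounds"]))


def fit_population_distribution(per_fruit, mmax_family: str = "truncnorm",
                                independent: bool = True) -> PopulationDistribution:
    """Fit the (Mmax, delta_t) population distribution to calibrated fruit.

    Marginal parameters are matched to the sample mean/sd; the Pearson
    correlation is recorded (and used unless ``independent`` — the default,
    since the two parameters show no correlation in the calibrated data).
    """
    if isinstance(per_fruit, dict):
        per_fruit = list(per_fruit.values())
    mmax = np.array([p.Mmax for p in per_fruit], dtype=float)
    dt = np.array([p.delta_t for p in per_fruit], dtype=float)
    if mmax.size < 10:
        raise ModelInputError("need at least 10 fruit to fit a population distribution")
    if np.std(mmax, ddof=1) <= 0 or np.std(dt, ddof=1) <= 0:
        raise ModelInputError("degenerate sample: zero variance")
    corr = float(np.corrcoef(mmax, dt)[0, 1])
    return PopulationDistribution(
        mmax_mean=float(np.mean(mmax)), mmax_sd=float(np.std(mmax, ddof=1)),
        dt_mean=float(np.mean(dt)), dt_sd=float(np.std(dt, ddof=1)),
        correlation=0.0 if independent else corr,
        mmax_family=mmax_family, provenance="fitted",
    )


def sample_population(dist: PopulationDistribution, N: int, seed: int) -> PopulationSample:
    """Draw N virtual fruit via a Gaussian copula; reproducible from the seed."""
    if N <= 0:
        raise ModelInputError("N must be positive")
    rng = np.random.default_rng(seed)
    rho = dist.correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=N, method="cholesky")
    u = stats.norm.cdf(z)
    # keep quantiles strictly inside (0, 1) for the ppf transforms
    eps = np.finfo(float).tiny
    u = np.clip(u, eps, 1 - 1e-16)
    mmax = dist._mmax_marginal().ppf(u[:, 0])
    dt = stats.norm.ppf(u[:, 1], loc=dist.dt_mean, scale=dist.dt_sd)
    return PopulationSample(mmax=mmax, delta_t=dt, seed=seed)


@dataclass
class PopulationTrajectories:
    """Per-fruit mass/hue trajectories of a virtual crop on the shared
    observation clock (each fruit's dynamics shifted by its delta_t).

    ``mass`` and ``hue`` are (N, T) matrices over ``t_grid``; ``state_at``
    evaluates the same solution at an arbitrary date.
    """

    growth: GrowthParams
    sample: PopulationSample
    t_grid: np.ndarray
    mass: np.ndarray
    hue: np.ndarray
    _clock: ColorClock = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.sample.n

    def state_at(self, t: float):
        """(mass, hue) vectors for all fruit at observation time ``t``."""
        ages = t + self.sample.delta_t
        g = self.growth
        mass = self.sample.mmax * np.exp(-g.C * np.exp(-g.km * ages))
        hue = self._clock.hue(ages)
        return mass, hue

    def total_mass_at(self, t: float, subset=None) -> float:
        mass, _ = self.state_at(t)
        return float(mass[subset].sum() if subset is not None else mass.sum())


def simulate_population(growth: GrowthParams, pop: PopulationSample, t_grid,
                        quad_step: float = 0.01) -> PopulationTrajectories:
    """Simulate every virtual fruit over ``t_grid`` (observation clock, d).

    Mass uses the Gompertz closed form; hue uses the exact integrating-factor
    solution with one shared quadrature of the colour-rate profile (the
    switch depends on mass only through M/Mmax, which is Mmax-free).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or not np.all(np.diff(t) > 0):
        raise ModelInputError("t_grid must be a strictly increasing 1-d array")
    ages = t[None, :] + pop.delta_t[:, None]
    clock = ColorClock(growth, float(ages.min()), float(ages.max()), step=quad_step)
    mass = pop.mmax[:, None] * np.exp(-growth.C * np.exp(-growth.km * ages))
    hue = clock.hue(ages)
    return PopulationTrajectories(growth=growth, sample=pop, t_grid=t,
                                  mass=mass, hue=hue, _clock=clock)


def stage_codes(hue, scheme: RipeningStageScheme) -> np.ndarray:
    """Integer stage codes: 0..5 for RS1..RS6, 6 for WASTE."""
    hue = np.asarray(hue, dtype=float)
    asc = np.array(scheme.lower_bounds[::-1])  # ascending edges
    return (6 - np.searchsorted(asc, hue, side="right")).astype(int)


def classify_stage(hue, scheme: RipeningStageScheme | None = None):
    """Stage label for a hue angle: 'RS1'..'RS6' or 'WASTE'.

    The waste class is strictly below the waste threshold (hue < 54 deg by
    default); a fruit exactly on a boundary belongs to the stage whose lower
    edge it is.
    """
    scheme = scheme or RipeningStageScheme()
    hue_arr = np.asarray(hue, dtype=float)
    if np.any(hue_arr <= 0) or np.any(hue_arr > 180):
        raise ModelInputError("hue must lie in (0, 180]")
    codes = stage_codes(hue_arr, scheme)
    labels = np.array(STAGE_LABELS + (WASTE,))[codes]
    return labels if labels.ndim else str(labels)


def stage_tally(traj: PopulationTrajectories, t: float,
                scheme: RipeningStageScheme | None = None,
                subset=None) -> dict:
    """Counts and total mass (g) per ripening stage (incl. WASTE) at time t."""
    scheme = scheme or RipeningStageScheme()
    mass, hue = traj.state_at(t)
    if subset is not None:
        mass, hue = mass[subset], hue[subset]
    codes = stage_codes(hue, scheme)
    counts = np.bincount(codes, minlength=7)
    masses = np.bincount(codes, weights=mass, minlength=7)
    labels = STAGE_LABELS + (WASTE,)
    return {
        "counts": dict(zip(labels, counts.astype(int))),
        "mass_g": dict(zip(labels, masses)),
    }
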