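"""Kinetic model of tomato fruit growth and ripening.

Fruit mass follows a Gompertz growth law,

    dM/dt = km * M * ln(Mmax / M),        M(0) = Mmax * exp(-C),

whose closed form is ``M(t) = Mmax * exp(-C * exp(-km * t))``.  Skin colour,
expressed as CIELAB hue angle H (degrees), decays exponentially toward a
minimum hue,

    dH/dt = -(H - Hmin) * kh,             H(0) = H0,

where the colour-change rate ``kh`` is modulated by a mass-dependent
biological switch,

    kh = kh_max / (1 + (Mmax - M) / Mmax)**s,

so that ripening is only triggered once the fruit approaches its final mass.
Time is measured on a per-fruit *biological age* clock; the observation clock
is converted to biological age by a fruit-specific shift, t_age = t_exp + Δt.

Internal canonical units are grams and days; the diameter-to-mass transform
at the measurement boundary works in SI (m, kg/m^3 -> kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

__all__ = [
    "DEFAULT_FRUIT_DENSITY",
    "GrowthParams",
    "FruitParams",
    "Trajectory",
    "ModelInputError",
    "IntegrationError",
    "mass_from_diameter",
    "hue_from_lab",
    "gompertz_mass",
    "switch_rate",
    "shift_time",
    "color_rate",
    "ColorClock",
    "simulate_fruit",
]

#: Average density of tomato fruit used for the sphere-volume mass estimate.
DEFAULT_FRUIT_DENSITY = 873.0  # kg/m^3


class ModelInputError(ValueError):
    """Raised when an input violates a model precondition."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a solution."""


@dataclass(frozen=True)
class GrowthParams:
    """Season/cultivar-level kinetic parameters.

    Attributes
    ----------
    C : float
        Dimensionless displacement factor of the Gompertz law (> 0).
    km : float
        Growth rate, 1/d (> 0).
    kh_max : float
        Maximum colour-change rate once ripening is fully triggered, 1/d (>= 0).
    H0 : float
        Initial (green) hue, degrees.
    Hmin : float
        Minimum (fully ripe) hue, degrees; H0 > Hmin.
    s : float
        Dimensionless steepness of the mass-triggered ripening switch (> 0).
    """

    C: float
    km: float
    kh_max: float
    H0: float
    Hmin: float
    s: float

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise ModelInputError(f"C must be > 0, got {self.C}")
        if not (self.km > 0):
            raise ModelInputError(f"km must be > 0, got {self.km}")
        if not (self.kh_max >= 0):
            raise ModelInputError(f"kh_max must be >= 0, got {self.kh_max}")
        if not (self.s > 0):
            raise ModelInputError(f"s must be > 0, got {self.s}")
        if not (self.H0 > self.Hmin):
            raise ModelInputError(
                f"H0 ({self.H0}) must exceed Hmin ({self.Hmin})"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParams":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})

    def replace(self, **kw) -> "GrowthParams":
        d = self.to_dict()
        d.update(kw)
        return GrowthParams(**d)


@dataclass(frozen=True)
class FruitParams:
    """Fruit-specific parameters: final mass and biological-age shift.

    Mmax is in grams, delta_t in days on the observation clock.
    """

    Mmax: float
    delta_t: float

    def __post_init__(self) -> None:
        if not (self.Mmax > 0):
            raise ModelInputError(f"Mmax must be > 0, got {self.Mmax}")
        if not math.isfinite(self.delta_t):
            raise ModelInputError(f"delta_t must be finite, got {self.delta_t}")

    def to_dict(self) -> dict:
        return {"Mmax": self.Mmax, "delta_t": self.delta_t}


@dataclass
class Trajectory:
    """A single fruit's simulated (biological-age, mass, hue) series."""

    times: np.ndarray  # d, strictly increasing
    mass: np.ndarray  # g
    hue: np.ndarray  # degrees

    def validate(self, growth: GrowthParams, fruit: FruitParams, tol: float = 1e-6) -> None:
        t, m, h = self.times, self.mass, self.hue
        if not np.all(np.diff(t) > 0):
            raise ModelInputError("trajectory times must be strictly increasing")
        slack_m = tol * fruit.Mmax
        if np.any(np.diff(m) < -slack_m):
            raise ModelInputError("mass must be non-decreasing")
        if np.any(m > fruit.Mmax * (1 + tol)) or np.any(m <= 0):
            raise ModelInputError("mass outside (0, Mmax]")
        slack_h = tol * (growth.H0 - growth.Hmin)
        if np.any(np.diff(h) > slack_h):
            raise ModelInputError("hue must be non-increasing")
        if np.any(h > growth.H0 + slack_h) or np.any(h < growth.Hmin - slack_h):
            raise ModelInputError("hue outside [Hmin, H0]")


def mass_from_diameter(diameter, density: float = DEFAULT_FRUIT_DENSITY):
    """Fruit mass (kg) from diameter (m), assuming a sphere of constant density.

    m = (4/3) * pi * (D/2)^3 * d, with d defaulting to 873 kg/m^3.
    """
    diameter = np.asarray(diameter, dtype=float)
    if np.any(diameter < 0):
        raise ModelInputError("diameter must be non-negative")
    if not density > 0:
        raise ModelInputError("density must be positive")
    m = (4.0 / 3.0) * np.pi * (diameter / 2.0) ** 3 * density
    return m if m.ndim else float(m)


def hue_from_lab(a_star, b_star):
    """Hue angle (degrees) from CIELAB a*, b*, quadrant-corrected to (0, 180].

    Uses the two-argument arctangent; negative angles are shifted by 180 deg
    so that green fruit (a* < 0) map above 90 deg and red fruit (a* > 0,
    b* > 0) below.  The pure red axis (a* > 0, b* = 0) maps to 0 deg.
    """
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if np.any((a == 0) & (b == 0)):
        raise ModelInputError("hue undefined for a* = b* = 0")
    ang = np.degrees(np.arctan2(b, a))
    ang = np.where(ang < 0, ang + 180.0, ang)
    return ang if ang.ndim else float(ang)


def gompertz_mass(t, Mmax: float, C: float, km: float):
    """Closed-form Gompertz mass M(t) = Mmax * exp(-C * exp(-km * t)) in g."""
    t = np.asarray(t, dtype=float)
    m = Mmax * np.exp(-C * np.exp(-km * t))
    return m if m.ndim else float(m)


def switch_rate(M, Mmax: float, kh_max: float, s: float):
    """Colour-change rate kh = kh_max / (1 + (Mmax - M)/Mmax)^s, 1/d.

    Evaluates the mass-triggered ripening switch: kh is negligible for small
    fruit (kh_max * 2^-s at M = 0) and reaches kh_max exactly at M = Mmax.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M > Mmax * (1 + 1e-12)):
        raise ModelInputError("M must lie in [0, Mmax]")
    kh = kh_max / (1.0 + (Mmax - M) / Mmax) ** s
    return kh if kh.ndim else float(kh)


def shift_time(t_exp, delta_t: float):
    """Biological age t_age = t_exp + delta_t (all in days)."""
    t = np.asarray(t_exp, dtype=float) + delta_t
    return t if t.ndim else float(t)


def color_rate(ages, growth: GrowthParams):
    """kh as a function of biological age.

    The switch depends on mass only through the ratio M/Mmax =
    exp(-C * exp(-km * t)), so this profile is shared by all fruit of a
    season regardless of their individual Mmax.
    """
    ages = np.asarray(ages, dtype=float)
    ratio = np.exp(-growth.C * np.exp(-growth.km * ages))
    return growth.kh_max / (2.0 - ratio) ** growth.s


class ColorClock:
    """Cumulative colour 'clock' K(t) = integral_0^t kh(tau) dtau.

    The exact hue solution of the colour ODE is
    H(t) = Hmin + (H0 - Hmin) * exp(-K(t)); this class tabulates K once by
    trapezoid quadrature on a fine grid and evaluates it (and the hue) by
    interpolation, which is shared across all fruit of a season.
    """

    def __init__(self, growth: GrowthParams, age_min: float, age_max: float,
                 step: float = 0.01):
        if age_max <= age_min:
            age_max = age_min + step
        lo = min(age_min, 0.0) - step
        hi = max(age_max, 0.0) + step
        n = max(int(np.ceil((hi - lo) / step)) + 1, 2)
        self.growth = growth
        self._grid = np.linspace(lo, hi, n)
        kh = color_rate(self._grid, growth)
        K = np.concatenate([[0.0], cumulative_trapezoid(kh, self._grid)])
        # anchor K(0) = 0 so H(0) = H0 on the biological-age clock
        self._K = K - np.interp(0.0, self._grid, K)

    def K(self, ages):
        ages = np.asarray(ages, dtype=float)
        k = np.interp(ages, self._grid, self._K)
        return k if k.ndim else float(k)

    def hue(self, ages):
        g = self.growth
        h = g.Hmin + (g.H0 - g.Hmin) * np.exp(-self.K(ages))
        return h if np.ndim(h) else float(h)

    def age_at_hue(self, hue: float) -> float:
        """Biological age at which the hue first drops to ``hue`` (monotone
        inversion on the tabulated grid)."""
        g = self.growth
        if not (g.Hmin < hue <= g.H0):
            raise ModelInputError(f"hue {hue} outside ({g.Hmin}, {g.H0}]")
        target_K = np.log((g.H0 - g.Hmin) / (hue - g.Hmin))
        if target_K > self._K[-1]:
            raise ModelInputError(
                f"hue {hue} not reached within the tabulated age range"
            )
        return float(np.interp(target_K, self._K, self._grid))


def simulate_fruit(growth: GrowthParams, fruit: FruitParams, t_grid,
                   rtol: float = 1e-8, atol: float = 1e-10,
                   max_step: float = 0.1) -> Trajectory:
    """Integrate the coupled (mass, hue) ODE system on a biological-age grid.

    The system is solved numerically as two states with an adaptive explicit
    Runge-Kutta scheme (the mass closed form is retained elsewhere as an
    independent oracle).  ``t_grid`` must be strictly increasing and start at
    or after biological age 0; integration always starts from the age-0
    initial condition (Mmax*exp(-C), H0).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or not np.all(np.diff(t) > 0):
        raise ModelInputError("t_grid must be a non-empty strictly increasing 1-d array")
    if t[0] < 0:
        raise ModelInputError("t_grid must start at or after biological age 0")

    Mmax, C, km = fruit.Mmax, growth.C, growth.km
    kh_max, s, Hmin = growth.kh_max, growth.s, growth.Hmin

    def rhs(_t, y):
        M, H = y
        M = min(max(M, 1e-300), Mmax)
        dM = km * M * np.log(Mmax / M) if M < Mmax else 0.0
        kh = kh_max / (1.0 + (Mmax - M) / Mmax) ** s
        dH = -(H - Hmin) * kh
        return [dM, dH]

    y0 = [Mmax * np.exp(-C), growth.H0]
    sol = solve_ivp(rhs, (0.0, float(t[-1])), y0, t_eval=t, method="RK45",
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=t, mass=sol.y[0], hue=sol.y[1])
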