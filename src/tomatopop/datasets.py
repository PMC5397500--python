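"""Published parameter sets and the wholesaler mixture-design survey.

These are the study-level inputs of the workflow: the calibrated
season-specific kinetic parameters, the fitted per-fruit parameter moments
used for Monte Carlo population generation, the 13-mixture wholesaler price
design with mean normalized prices, and the fitted mixture-model price
coefficients for both growing seasons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import GrowthParams

__all__ = [
    "WINTER_GROWTH",
    "SUMMER_GROWTH",
    "growth_params",
    "POPULATION_MOMENTS",
    "COHORT_SIZE",
    "MIXTURE_DESIGN",
    "PRICE_COEFFS_TABLE",
    "mixture_design",
    "mean_prices",
]

#: Winter-season shared kinetic parameters (cv. "Savior", n = 342 fruit).
WINTER_GROWTH = GrowthParams(C=4.87, km=0.0702, kh_max=26.02,
                             H0=105.74, Hmin=52.55, s=54.30)

#: Summer-season shared kinetic parameters (n = 370 fruit).
SUMMER_GROWTH = GrowthParams(C=9.76, km=0.11, kh_max=14.83,
                             H0=106.63, Hmin=51.37, s=33.39)

#: Moments of the fitted per-fruit parameters: (mean, sd) of Mmax in g and
#: of the biological shift delta_t in d, per season.
POPULATION_MOMENTS = {
    "winter": {"Mmax": (107.1, 36.9), "delta_t": (7.01, 2.82)},
    "summer": {"Mmax": (99.03, 28.39), "delta_t": (5.39, 2.12)},
}

#: Number of successfully monitored fruit per season.
COHORT_SIZE = {"winter": 342, "summer": 370}


def growth_params(season: str) -> GrowthParams:
    try:
        return {"winter": WINTER_GROWTH, "summer": SUMMER_GROWTH}[season]
    except KeyError:
        raise ValueError(f"unknown season {season!r}; expected winter/summer") from None


# 13-mixture wholesaler survey design: ripening-stage fractions of each batch
# and the mean normalized price/kg given by the 30-wholesaler panel.
_MIXTURES = [
    # mixture, rs6, rs5, rs4, rs3, rs2, rs1, winter, summer
    (1, 1.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 1.00),
    (2, 0.00, 1.00, 0.00, 0.00, 0.00, 0.00, 0.98, 0.97),
    (3, 0.00, 0.00, 1.00, 0.00, 0.00, 0.00, 0.93, 0.73),
    (4, 0.00, 0.00, 0.00, 1.00, 0.00, 0.00, 0.51, 0.61),
    (5, 0.00, 0.00, 0.00, 0.00, 1.00, 0.00, 0.36, 0.30),
    (6, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.00, 0.00),
    (7, 0.25, 0.25, 0.25, 0.25, 0.00, 0.00, 0.63, 0.62),
    (8, 0.20, 0.20, 0.20, 0.20, 0.20, 0.00, 0.54, 0.52),
    (9, 0.00, 0.20, 0.20, 0.20, 0.20, 0.20, 0.49, 0.47),
    (10, 0.10, 0.30, 0.30, 0.15, 0.10, 0.05, 0.54, 0.50),
    (11, 0.10, 0.30, 0.20, 0.10, 0.10, 0.20, 0.50, 0.50),
    (12, 0.10, 0.50, 0.40, 0.00, 0.00, 0.00, 0.66, 0.62),
    (13, 0.10, 0.20, 0.20, 0.20, 0.20, 0.10, 0.47, 0.48),
]

MIXTURE_DESIGN = pd.DataFrame(
    _MIXTURES,
    columns=["mixture", "rs6", "rs5", "rs4", "rs3", "rs2", "rs1",
             "price_winter", "price_summer"],
).set_index("mixture")

#: Published mixture-model coefficients (estimate, se) per season, in the
#: canonical design order rs1..rs6, rs1*rs6, rs2*rs6, rs1*rs5.
PRICE_COEFFS_TABLE = {
    "winter": {
        "estimate": np.array([0.00, 0.35, 0.47, 0.81, 0.84, 0.94,
                              -3.21, -4.11, -0.21]),
        "se": np.array([0.03, 0.03, 0.03, 0.03, 0.03, 0.03,
                        2.90, 0.88, 0.88]),
    },
    "summer": {
        "estimate": np.array([0.00, 0.29, 0.57, 0.62, 0.85, 0.95,
                              -2.33, -3.66, -0.10]),
        "se": np.array([0.03, 0.03, 0.03, 0.03, 0.03, 0.03,
                        2.86, 0.86, 0.87]),
    },
}


def mixture_design() -> pd.DataFrame:
    """The 13 mixture compositions, columns rs1..rs6 in canonical order."""
    return MIXTURE_DESIGN[["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"]].copy()


def mean_prices(season: str) -> pd.Series:
    """Mean normalized price/kg per mixture for one season."""
    col = {"winter": "price_winter", "summer": "price_summer"}[season]
    return MIXTURE_DESIGN[col].rename("normalized_price")
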