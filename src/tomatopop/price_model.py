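"""Wholesaler price model for mixed-maturity tomato batches.

A batch is described by the fractions of its six ripening stages (a mixture
design: fractions sum to 1, so the regression carries no intercept).  The
normalized price per kg is modeled as

    Y = a1*RS1 + ... + a6*RS6 + a7*RS1*RS6 + a8*RS2*RS6 + a9*RS1*RS5,

with interaction terms only for the most dissimilar maturity classes.  Raw
survey prices are first min-max normalized to [0, 1] within each
rater x season group so raters and seasons are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DESIGN_COLUMNS",
    "RS_COLUMNS",
    "PriceObservation",
    "PriceCoefficients",
    "InvalidCompositionError",
    "DegenerateGroupError",
    "normalize_prices",
    "build_design_matrix",
    "fit_price_model",
    "predict_price",
]

logger = logging.getLogger(__name__)

RS_COLUMNS = ("rs1", "rs2", "rs3", "rs4", "rs5", "rs6")
#: Fixed column order of the no-intercept design matrix.
DESIGN_COLUMNS = RS_COLUMNS + ("rs1_rs6", "rs2_rs6", "rs1_rs5")

_SUM_TOL = 1e-9


class InvalidCompositionError(ValueError):
    """Composition fractions are negative or do not sum to 1."""


class DegenerateGroupError(ValueError):
    """A rater x season group has no price spread to normalize."""


@dataclass(frozen=True)
class PriceObservation:
    """One rater's price for one batch composition."""

    rater_id: str
    season: str
    composition: tuple  # fractions rs1..rs6
    raw_price: float = float("nan")
    normalized_price: float = float("nan")

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        _check_compositions(comp[None, :])
        object.__setattr__(self, "composition", tuple(comp))


@dataclass
class PriceCoefficients:
    """Fitted mixture-model coefficients in DESIGN_COLUMNS order."""

    alphas: np.ndarray
    se: np.ndarray | None = None
    p_values: np.ndarray | None = None
    r_squared: float = float("nan")  # uncentered (no-intercept convention)
    r_squared_centered: float = float("nan")
    season: str = ""

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.shape != (9,):
            raise ValueError("expected 9 coefficients")

    def to_dict(self) -> dict:
        d = {"season": self.season, "r_squared": self.r_squared,
             "r_squared_centered": self.r_squared_centered,
             "coefficients": dict(zip(DESIGN_COLUMNS, self.alphas))}
        if self.se is not None:
            d["se"] = dict(zip(DESIGN_COLUMNS, np.asarray(self.se, dtype=float)))
        if self.p_values is not None:
            d["p_values"] = dict(zip(DESIGN_COLUMNS, np.asarray(self.p_values, dtype=float)))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriceCoefficients":
        co = d["coefficients"]
        return cls(
            alphas=np.array([co[c] for c in DESIGN_COLUMNS], dtype=float),
            se=(np.array([d["se"][c] for c in DESIGN_COLUMNS], dtype=float)
                if "se" in d else None),
            p_values=(np.array([d["p_values"][c] for c in DESIGN_COLUMNS], dtype=float)
                      if "p_values" in d else None),
            r_squared=d.get("r_squared", float("nan")),
            r_squared_centered=d.get("r_squared_centered", float("nan")),
            season=d.get("season", ""),
        )

    @classmethod
    def from_published(cls, season: str) -> "PriceCoefficients":
        from .datasets import PRICE_COEFFS_TABLE
        t = PRICE_COEFFS_TABLE[season]
        return cls(alphas=t["estimate"].copy(), se=t["se"].copy(), season=season)


def _check_compositions(comp: np.ndarray) -> None:
    if np.any(comp < -_SUM_TOL):
        raise InvalidCompositionError("stage fractions must be non-negative")
    bad = np.abs(comp.sum(axis=1) - 1.0) > _SUM_TOL
    if np.any(bad):
        raise InvalidCompositionError(
            f"{int(bad.sum())} composition(s) do not sum to 1 within {_SUM_TOL}"
        )


def normalize_prices(survey: pd.DataFrame, price_col: str = "raw_price",
                     group_cols=("rater_id", "season")) -> pd.DataFrame:
    """Min-max normalize prices to [0, 1] within each rater x season group."""
    out = survey.copy()

    def _scale(g: pd.Series) -> pd.Series:
        lo, hi = g.min(), g.max()
        if hi <= lo:
            raise DegenerateGroupError(
                f"constant prices in group {g.name}; cannot normalize")
        return (g - lo) / (hi - lo)

    out["normalized_price"] = (
        out.groupby(list(group_cols), sort=False)[price_col].transform(_scale)
    )
    return out


def build_design_matrix(compositions) -> pd.DataFrame:
    """No-intercept design matrix with columns :data:`DESIGN_COLUMNS`.

    ``compositions`` is an (n, 6) array or a DataFrame with rs1..rs6 columns;
    each row must be a valid mixture (non-negative, summing to 1).
    """
    if isinstance(compositions, pd.DataFrame):
        comp = compositions.loc[:, list(RS_COLUMNS)].to_numpy(dtype=float)
        index = compositions.index
    else:
        comp = np.atleast_2d(np.asarray(compositions, dtype=float))
        index = None
    if comp.shape[1] != 6:
        raise InvalidCompositionError("expected 6 stage fractions per row")
    _check_compositions(comp)
    rs1, rs2, rs5, rs6 = comp[:, 0], comp[:, 1], comp[:, 4], comp[:, 5]
    X = np.column_stack([comp, rs1 * rs6, rs2 * rs6, rs1 * rs5])
    return pd.DataFrame(X, columns=list(DESIGN_COLUMNS), index=index)


def fit_price_model(survey: pd.DataFrame, response: str = "normalized_price",
                    by_rater: bool = False):
    """Ordinary least squares fit of the mixture model (no intercept).

    ``survey`` needs rs1..rs6 columns and the response column.  Standard
    errors and p-values come from standard linear-model theory; R^2 is the
    uncentered definition appropriate for a no-intercept model (the centered
    value is also reported).  With ``by_rater=True`` a dict of per-rater fits
    is returned.
    """
    if by_rater:
        return {rid: fit_price_model(g, response=response)
                for rid, g in survey.groupby("rater_id", sort=False)}
    X = build_design_matrix(survey)
    y = survey[response].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        pairs = [
            (DESIGN_COLUMNS[i], DESIGN_COLUMNS[j])
            for i in range(9) for j in range(i + 1, 9)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise np.linalg.LinAlgError(
            f"design matrix rank deficient (rank {rank} < 9); "
            f"collinear columns: {pairs}"
        )
    res = sm.OLS(y, X.to_numpy()).fit()
    yc = y - y.mean()
    r2_centered = 1.0 - res.ssr / float(yc @ yc) if yc @ yc > 0 else float("nan")
    season = ""
    if "season" in survey.columns and survey["season"].nunique() == 1:
        season = str(survey["season"].iloc[0])
    return PriceCoefficients(
        alphas=res.params, se=res.bse, p_values=res.pvalues,
        r_squared=float(res.rsquared),  # uncentered when no intercept
        r_squared_centered=float(r2_centered), season=season,
    )


def predict_price(coeffs: PriceCoefficients, composition) -> float | np.ndarray:
    """Normalized price/kg predicted for a batch composition (rs1..rs6).

    Predictions are not clipped to [0, 1]; out-of-range values are flagged in
    the log.
    """
    X = build_design_matrix(composition)
    y = X.to_numpy() @ coeffs.alphas
    if np.any((y < -1e-9) | (y > 1 + 1e-9)):
        logger.warning("predicted normalized price outside [0, 1]: %s",
                       y[(y < -1e-9) | (y > 1 + 1e-9)])
    return y if y.size > 1 else float(y[0])
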