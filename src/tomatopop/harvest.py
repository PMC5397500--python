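"""Harvest strategies over a simulated fruit population and their economics.

On each harvest date, fruit currently in the targeted ripening stages are
removed at their current mass; overripe fruit encountered on a harvest date
are removed as unsaleable waste.  Each harvest event is valued by the
mixture price model applied to the stage composition of its saleable mass,
and event values are cumulated (no discounting) into the total economic value
of a strategy, in units of normalized-price x kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ModelInputError
from .population import (
    STAGE_LABELS,
    WASTE,
    PopulationTrajectories,
    RipeningStageScheme,
    stage_codes,
)
from .price_model import PriceCoefficients, predict_price

__all__ = [
    "HarvestStrategy",
    "HarvestEvent",
    "HarvestOutcome",
    "apply_harvest_strategy",
    "single_harvest_sweep",
    "compare_strategies",
]

_MODES = ("single", "fixed_interval", "dynamic")


@dataclass(frozen=True)
class HarvestStrategy:
    """A harvest plan inside a [window_start, window_end] window (days).

    * ``single`` — one harvest of all non-waste fruit, at ``schedule[0]``;
    * ``fixed_interval`` — harvests of ``target_stages`` every ``interval``
      days from window_start;
    * ``dynamic`` — harvests of ``target_stages`` at the explicit
      ``schedule`` dates.
    """

    mode: str
    window_start: float
    window_end: float
    target_stages: tuple = ("RS5", "RS6")
    interval: float | None = None
    schedule: tuple = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ModelInputError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.window_end <= self.window_start:
            raise ModelInputError("window_end must exceed window_start")
        object.__setattr__(self, "target_stages", tuple(self.target_stages))
        object.__setattr__(self, "schedule", tuple(float(t) for t in self.schedule))
        bad = set(self.target_stages) - set(STAGE_LABELS)
        if bad:
            raise ModelInputError(f"unknown target stages: {sorted(bad)}")
        if self.mode == "single":
            if len(self.schedule) != 1:
                raise ModelInputError("single mode needs exactly one schedule date")
        elif self.mode == "fixed_interval":
            if self.interval is None or self.interval < 1.0:
                raise ModelInputError("fixed_interval mode needs interval >= 1 d")
            if not self.target_stages:
                raise ModelInputError("target_stages must be non-empty")
        else:  # dynamic
            if not self.schedule or np.any(np.diff(self.schedule) <= 0):
                raise ModelInputError("dynamic mode needs a strictly increasing schedule")
            if not self.target_stages:
                raise ModelInputError("target_stages must be non-empty")
        lo, hi = self.window_start, self.window_end
        if self.schedule and (min(self.schedule) < lo or max(self.schedule) > hi):
            raise ModelInputError("schedule dates must lie within the window")
        if not self.name:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        stages = "+".join(self.target_stages)
        if self.mode == "single":
            return f"single@{self.schedule[0]:g}d"
        if self.mode == "fixed_interval":
            return f"{stages} every {self.interval:g}d"
        return f"{stages} dynamic({len(self.schedule)} dates)"

    def dates(self) -> np.ndarray:
        if self.mode == "fixed_interval":
            return np.arange(self.window_start, self.window_end + 1e-9, self.interval)
        return np.asarray(self.schedule, dtype=float)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "window_start": self.window_start,
                "window_end": self.window_end,
                "target_stages": list(self.target_stages),
                "interval": self.interval, "schedule": list(self.schedule),
                "name": self.name}

    @classmethod
    def from_dict(cls, d: dict) -> "HarvestStrategy":
        d = dict(d)
        d["target_stages"] = tuple(d.get("target_stages", ("RS5", "RS6")))
        d["schedule"] = tuple(d.get("schedule", ()))
        return cls(**d)


@dataclass
class HarvestEvent:
    date: float
    harvested_ids: np.ndarray
    waste_ids: np.ndarray  # fruit removed overripe on this date
    mass_by_stage: dict  # g, saleable stages only
    waste_mass: float  # g removed as overripe
    composition: np.ndarray  # fractions rs1..rs6 over saleable mass
    price: float  # normalized price / kg
    saleable_mass: float  # g
    value: float  # price * saleable kg


@dataclass
class HarvestOutcome:
    strategy: HarvestStrategy
    events: list
    cumulative_value: float
    total_saleable_mass: float  # g
    total_waste_mass: float  # g
    unharvested_ids: np.ndarray
    unharvested_mass: float  # g, at window end

    @property
    def n_harvests(self) -> int:
        return sum(1 for e in self.events if e.saleable_mass > 0)


def _empty_composition() -> np.ndarray:
    return np.zeros(6)


def apply_harvest_strategy(traj: PopulationTrajectories,
                           strategy: HarvestStrategy,
                           scheme: RipeningStageScheme | None = None,
                           coeffs: PriceCoefficients | None = None,
                           remove_waste: bool = True) -> HarvestOutcome:
    """Run one strategy over the population and account value and waste.

    Fruit are assessed at their exact state on each harvest date (no
    look-ahead); harvested fruit are removed and never revisited, the rest
    continue to develop.  Overripe fruit found on a harvest date are removed
    as waste (mass counted, value zero) unless ``remove_waste`` is False.
    """
    scheme = scheme or RipeningStageScheme()
    if coeffs is None:
        coeffs = PriceCoefficients.from_published("winter")
    dates = strategy.dates()
    if dates.size and (dates[0] < traj.t_grid[0] - 1e-9 or dates[-1] > traj.t_grid[-1] + 1e-9):
        raise ModelInputError("harvest schedule outside the simulated window")

    remaining = np.ones(traj.n, dtype=bool)
    events: list[HarvestEvent] = []
    total_value = total_saleable = total_waste = 0.0
    target_codes = {STAGE_LABELS.index(st) for st in strategy.target_stages}

    for date in dates:
        mass, hue = traj.state_at(float(date))
        codes = stage_codes(hue, scheme)
        waste_mask = remaining & (codes == 6)
        if strategy.mode == "single":
            take = remaining & (codes < 6)
        else:
            take = remaining & np.isin(codes, list(target_codes))

        waste_mass = float(mass[waste_mask].sum()) if remove_waste else 0.0
        saleable_mass = float(mass[take].sum())
        if saleable_mass > 0:
            stage_mass = np.bincount(codes[take], weights=mass[take], minlength=7)[:6]
            composition = stage_mass / saleable_mass
            price = float(predict_price(coeffs, composition[None, :]))
        else:
            stage_mass = np.zeros(6)
            composition = _empty_composition()
            price = 0.0
        value = price * saleable_mass / 1000.0  # g -> kg

        events.append(HarvestEvent(
            date=float(date), harvested_ids=np.flatnonzero(take),
            waste_ids=np.flatnonzero(waste_mask) if remove_waste
            else np.array([], dtype=int),
            mass_by_stage=dict(zip(STAGE_LABELS, stage_mass)),
            waste_mass=waste_mass, composition=composition,
            price=price, saleable_mass=saleable_mass, value=value,
        ))
        total_value += value
        total_saleable += saleable_mass
        total_waste += waste_mass
        remaining &= ~take
        if remove_waste:
            remaining &= ~waste_mask

    unharvested = np.flatnonzero(remaining)
    unharvested_mass = traj.total_mass_at(strategy.window_end, subset=remaining)
    return HarvestOutcome(
        strategy=strategy, events=events, cumulative_value=total_value,
        total_saleable_mass=total_saleable, total_waste_mass=total_waste,
        unharvested_ids=unharvested, unharvested_mass=unharvested_mass,
    )


def single_harvest_sweep(traj: PopulationTrajectories, window,
                         scheme: RipeningStageScheme | None = None,
                         coeffs: PriceCoefficients | None = None,
                         step: float = 1.0) -> pd.DataFrame:
    """Evaluate a single whole-crop harvest at every candidate date.

    ``window`` is (start, end) in days on the observation clock.  Returns a
    DataFrame with columns date, value, saleable_mass_g, waste_mass_g; the
    attribute ``df.attrs['optimal_date']`` holds the argmax-value date.
    """
    scheme = scheme or RipeningStageScheme()
    if coeffs is None:
        coeffs = PriceCoefficients.from_published("winter")
    start, end = float(window[0]), float(window[1])
    if start < traj.t_grid[0] - 1e-9 or end > traj.t_grid[-1] + 1e-9:
        raise ModelInputError("sweep window outside the simulated grid")
    dates = np.arange(start, end + 1e-9, step)
    rows = []
    for date in dates:
        mass, hue = traj.state_at(float(date))
        codes = stage_codes(hue, scheme)
        waste = codes == 6
        saleable_mass = float(mass[~waste].sum())
        waste_mass = float(mass[waste].sum())
        if saleable_mass > 0:
            stage_mass = np.bincount(codes[~waste], weights=mass[~waste], minlength=7)[:6]
            price = float(predict_price(coeffs, (stage_mass / saleable_mass)[None, :]))
        else:
            price = 0.0
        rows.append((float(date), price * saleable_mass / 1000.0,
                     saleable_mass, waste_mass))
    df = pd.DataFrame(rows, columns=["date", "value", "saleable_mass_g", "waste_mass_g"])
    df.attrs["optimal_date"] = float(df.loc[df["value"].idxmax(), "date"])
    return df


def compare_strategies(traj: PopulationTrajectories, strategies,
                       scheme: RipeningStageScheme | None = None,
                       coeffs: PriceCoefficients | None = None):
    """Evaluate strategies on a common population; rank by cumulative value.

    Returns ``(table, outcomes)``: a DataFrame sorted by value (descending)
    and the full per-strategy :class:`HarvestOutcome` objects keyed by
    strategy name, whose events give the per-harvest value breakdown.
    """
    outcomes = {}
    rows = []
    for strat in strategies:
        out = apply_harvest_strategy(traj, strat, scheme=scheme, coeffs=coeffs)
        outcomes[strat.name] = out
        rows.append({
            "strategy": strat.name, "mode": strat.mode,
            "target_stages": "+".join(strat.target_stages),
            "n_harvests": out.n_harvests,
            "cumulative_value": out.cumulative_value,
            "saleable_mass_g": out.total_saleable_mass,
            "waste_mass_g": out.total_waste_mass,
            "unharvested_mass_g": out.unharvested_mass,
        })
    table = pd.DataFrame(rows).sort_values(
        "cumulative_value", ascending=False, ignore_index=True)
    best = table["cumulative_value"].max()
    table["relative_value"] = table["cumulative_value"] / best if best > 0 else np.nan
    return table, outcomes


def event_breakdown(outcomes: dict) -> pd.DataFrame:
    """Long-form per-event table (strategy, event date, value, masses)."""
    rows = []
    for name, out in outcomes.items():
        for i, e in enumerate(out.events):
            rows.append({"strategy": name, "event": i + 1, "date": e.date,
                         "value": e.value, "price": e.price,
                         "saleable_mass_g": e.saleable_mass,
                         "waste_mass_g": e.waste_mass})
    return pd.DataFrame(rows)
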