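"""Plain-text I/O: CSV observation tables, JSON parameter sets, provenance.

Observation CSVs carry columns ``fruit_id, season, t_exp_d`` plus either
``mass_g`` or ``diameter_m`` (converted on load via the sphere-volume
transform) and either ``hue_deg`` or CIELAB ``L, a, b`` (converted via the
two-argument arctangent).  Parameter sets are JSON objects keyed by symbol
names; strategies load from JSON or YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationResult, ObservationSeries
from .core_model import FruitParams, GrowthParams, hue_from_lab, mass_from_diameter
from .harvest import HarvestStrategy
from .population import PopulationDistribution, RipeningStageScheme

__all__ = [
    "observations_to_frame",
    "frame_to_observations",
    "load_observations",
    "save_observations",
    "load_growth_params",
    "save_growth_params",
    "save_calibration_result",
    "load_per_fruit",
    "load_strategies",
    "load_scheme",
    "load_distribution",
    "save_json",
    "write_provenance",
]


def observations_to_frame(series) -> pd.DataFrame:
    frames = []
    for o in series:
        frames.append(pd.DataFrame({
            "fruit_id": o.fruit_id, "season": o.season,
            "t_exp_d": o.t_exp, "mass_g": o.mass_obs, "hue_deg": o.hue_obs,
        }))
    return pd.concat(frames, ignore_index=True)


def frame_to_observations(df: pd.DataFrame) -> list:
    df = df.copy()
    if "mass_g" not in df.columns:
        if "diameter_m" not in df.columns:
            raise ValueError("need a mass_g or diameter_m column")
        df["mass_g"] = mass_from_diameter(df["diameter_m"].to_numpy()) * 1000.0
    if "hue_deg" not in df.columns:
        if not {"a", "b"} <= set(df.columns):
            raise ValueError("need a hue_deg column or CIELAB a, b columns")
        df["hue_deg"] = hue_from_lab(df["a"].to_numpy(), df["b"].to_numpy())
    if "season" not in df.columns:
        df["season"] = ""
    out = []
    for fid, g in df.groupby("fruit_id", sort=False):
        g = g.sort_values("t_exp_d")
        out.append(ObservationSeries(
            fruit_id=str(fid), t_exp=g["t_exp_d"].to_numpy(dtype=float),
            mass_obs=g["mass_g"].to_numpy(dtype=float),
            hue_obs=g["hue_deg"].to_numpy(dtype=float),
            season=str(g["season"].iloc[0]),
        ))
    return out


def load_observations(path) -> list:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse observation CSV {path}: {exc}") from exc
    required = {"fruit_id", "t_exp_d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame_to_observations(df)


def save_observations(series, path) -> None:
    observations_to_frame(series).to_csv(path, index=False)


def load_growth_params(path) -> GrowthParams:
    with open(path) as fh:
        return GrowthParams.from_dict(json.load(fh))


def save_growth_params(params: GrowthParams, path) -> None:
    save_json(params.to_dict(), path)


def save_calibration_result(result: CalibrationResult, json_path, per_fruit_csv) -> None:
    payload = {
        "shared": result.shared.to_dict(),
        "shared_se": result.shared_se,
        "rss": result.rss,
        "r_squared": result.r_squared,
        "converged": result.converged,
        "n_outer": result.n_outer,
        "normalization": result.normalization.to_dict(),
        "excluded": result.excluded,
        "n_fruit": len(result.per_fruit),
        "mean_Mmax": result.mean_mmax(),
        "mean_delta_t": result.mean_delta_t(),
    }
    save_json(payload, json_path)
    rows = [{"fruit_id": fid, "Mmax": p.Mmax, "delta_t": p.delta_t}
            for fid, p in result.per_fruit.items()]
    pd.DataFrame(rows).to_csv(per_fruit_csv, index=False)


def load_per_fruit(csv_path) -> dict:
    df = pd.read_csv(csv_path)
    return {str(r.fruit_id): FruitParams(Mmax=float(r.Mmax), delta_t=float(r.delta_t))
            for r in df.itertuples()}


def _load_structured(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def load_strategies(path) -> list:
    """Strategy definitions from a JSON/YAML file: a list (or a dict with a
    'strategies' key) of HarvestStrategy mappings."""
    data = _load_structured(path)
    if isinstance(data, dict):
        data = data.get("strategies", [data])
    return [HarvestStrategy.from_dict(d) for d in data]


def load_scheme(path) -> RipeningStageScheme:
    return RipeningStageScheme.from_dict(_load_structured(path))


def load_distribution(path) -> PopulationDistribution:
    return PopulationDistribution.from_dict(_load_structured(path))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def write_provenance(out_dir, command: str, config: dict) -> None:
    """Record enough (command, config hash, seed, version) to reproduce a run."""
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "command": command,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "tomatopop_version": __version__,
    }
    save_json(record, Path(out_dir) / f"provenance_{command}.json")
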