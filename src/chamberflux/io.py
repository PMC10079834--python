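"""CSV dialects and configuration loading.

All artifacts are plain CSV with a header row, UTF-8, ISO-8601 UTC
timestamps.  Readers validate required columns (naming what is missing),
tolerate and preserve extra columns, and every writer's output is readable
by the matching reader (schema closure).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .fluxfit import Deployment

DEPLOYMENT_COLUMNS = [
    "deployment_id",
    "chamber_id",
    "timestamp",
    "gas",
    "mole_fraction",
    "unit",
    "cavity_temp_k",
    "cavity_press_kpa",
    "collar_area_m2",
    "volume_m3",
]
FLUX_COLUMNS = [
    "deployment_id",
    "chamber_id",
    "timestamp",
    "gas",
    "flux_mass",
    "flux_molar",
    "model",
    "uncertainty_ratio",
    "r_squared",
    "below_mdf",
    "qc_flags",
]
SENSOR_COLUMNS = ["timestamp", "depth_cm", "variable", "value"]
VEGETATION_COLUMNS = ["date", "ndvi", "nir", "nirv"]
NEE_COLUMNS = ["site_year", "nee", "reco", "gpp"]
TRUTH_COLUMNS = ["timestamp", "gas", "true_flux", "hot_indicator", "hot_component"]


def _require(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing columns: {', '.join(missing)}")


def _parse_timestamps(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    try:
        return pd.to_datetime(df[col], format="ISO8601", utc=False)
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{what} file: malformed timestamp {df[col].iloc[row]!r} at row {row}"
            ) from None
        return parsed


def write_deployments_csv(deployments: Iterable[Deployment], path) -> None:
    frames = []
    for dep in deployments:
        stamps = dep.start_time + pd.to_timedelta(dep.time_s, unit="s")
        n = dep.time_s.size
        frames.append(
            pd.DataFrame(
                {
                    "deployment_id": dep.deployment_id,
                    "chamber_id": dep.chamber_id,
                    "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                    "gas": dep.gas,
                    "mole_fraction": dep.mole_fraction_ppm,
                    "unit": "ppm",
                    "cavity_temp_k": np.resize(dep.cavity_temp_k, n),
                    "cavity_press_kpa": np.resize(dep.cavity_press_kpa, n),
                    "collar_area_m2": dep.collar_area_m2,
                    "volume_m3": dep.volume_m3,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_deployments_csv(path) -> List[Deployment]:
    df = pd.read_csv(path)
    _require(df, DEPLOYMENT_COLUMNS, "deployments")
    df["timestamp"] = _parse_timestamps(df, "timestamp", "deployments")
    from .units import mole_fraction_to_ppm

    deployments = []
    for (dep_id, gas), grp in df.groupby(["deployment_id", "gas"], sort=False):
        grp = grp.sort_values("timestamp")
        start = grp["timestamp"].iloc[0]
        time_s = (grp["timestamp"] - start).dt.total_seconds().to_numpy()
        unit = str(grp["unit"].iloc[0])
        deployments.append(
            Deployment(
                deployment_id=str(dep_id),
                chamber_id=str(grp["chamber_id"].iloc[0]),
                gas=str(gas),
                time_s=time_s,
                mole_fraction_ppm=mole_fraction_to_ppm(
                    grp["mole_fraction"].to_numpy(dtype=float), unit
                ),
                cavity_temp_k=grp["cavity_temp_k"].to_numpy(dtype=float),
                cavity_press_kpa=grp["cavity_press_kpa"].to_numpy(dtype=float),
                collar_area_m2=float(grp["collar_area_m2"].iloc[0]),
                volume_m3=float(grp["volume_m3"].iloc[0]),
                start_time=start,
                unit=unit,
            )
        )
    return deployments


def write_fluxes_csv(fluxes: pd.DataFrame, path) -> None:
    fluxes.to_csv(path, index=False)


def read_fluxes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, FLUX_COLUMNS, "fluxes")
    df["timestamp"] = _parse_timestamps(df, "timestamp", "fluxes")
    return df


def read_sensors_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SENSOR_COLUMNS, "sensors")
    df["timestamp"] = _parse_timestamps(df, "timestamp", "sensors")
    return df


def read_vegetation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, VEGETATION_COLUMNS, "vegetation")
    df["date"] = _parse_timestamps(df, "date", "vegetation")
    return df


def read_nee_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, NEE_COLUMNS, "NEE")
    return df


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRUTH_COLUMNS, "ground-truth")
    df["timestamp"] = _parse_timestamps(df, "timestamp", "ground-truth")
    return df


def load_yaml_config(path) -> Dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError("config file must hold a mapping")
    return data
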