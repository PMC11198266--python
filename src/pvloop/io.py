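"""File formats and run configuration.

Volume curves travel as two-column CSV (``time_s,volume_ml``) with optional
``#``-prefixed metadata lines (``# heart_rate_bpm=72``).  Cohort tables are
flat CSV with booleans coded 0/1 and etiology as ``ICM``/``NIDCM``.
Per-patient parameter output is JSON.  All defaults resolve without any
external file.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .cohort import CohortConfig
from .elastance import VolumeTimeSeries
from .metrics import PVParameters

__all__ = [
    "RunConfig",
    "ParseError",
    "read_volume_series",
    "write_volume_series",
    "read_elastance_curve",
    "read_cohort",
    "write_cohort",
    "parameters_to_dict",
]

BOOL_COLUMNS = ("male", "hypertension", "diabetes", "event")
ETIOLOGY_LABELS = {"ICM", "NIDCM"}


class ParseError(ValueError):
    """A file does not conform to the declared format."""


class RunConfig(BaseModel):
    """Pipeline-wide settings; every default resolves without external files."""

    model_config = ConfigDict(extra="forbid")

    edp_mmhg: float = 7.0
    v0_ml: float = 0.0
    bsa_m2: float = 1.9
    peak_pressure_method: str = "identity"
    peak_pressure_c1: float = 1.0
    peak_pressure_c0: float = 0.0
    elastance_baseline: float = 0.05
    elastance_curve_csv: Optional[str] = None
    cohort: CohortConfig = CohortConfig()
    output_dir: str = "pvloop_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def read_volume_series(path: str | Path) -> VolumeTimeSeries:
    """Read one cardiac cycle of volumes from CSV.

    Expects header ``time_s,volume_ml``; rows are sorted by time.  Metadata
    comment lines of the form ``# key=value`` may carry ``heart_rate_bpm``;
    if absent the heart rate is inferred from the cycle duration.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        header_lines = [ln for ln in fh if ln.startswith("#")]
    for ln in header_lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()

    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "volume_ml"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df = df.sort_values("time_s").reset_index(drop=True)
    times = df["time_s"].to_numpy(dtype=float)
    volumes = df["volume_ml"].to_numpy(dtype=float)
    if len(df) < 20:
        raise ParseError(f"{path}: need at least 20 frames, found {len(df)}")
    if np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}: duplicate or nonmonotone times")
    if np.all(volumes < 1.0):
        warnings.warn(
            f"{path}: all volumes are below 1; expected millilitres — are these litres?"
        )
    if "heart_rate_bpm" in meta:
        hr = float(meta["heart_rate_bpm"])
    else:
        hr = 60.0 / (times[-1] - times[0])
    try:
        return VolumeTimeSeries(times=times - times[0], volumes=volumes, heart_rate=hr)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_volume_series(vts: VolumeTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# heart_rate_bpm={vts.heart_rate:.6g}\n")
        fh.write("time_s,volume_ml\n")
        for t, v in zip(vts.times, vts.volumes):
            fh.write(f"{t:.6f},{v:.6f}\n")


def read_elastance_curve(path: str | Path):
    """Read a digitized normalized-elastance waveform (``t_norm,e_norm`` CSV)."""
    from .elastance import elastance_from_samples

    df = pd.read_csv(path, comment="#")
    for col in ("t_norm", "e_norm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return elastance_from_samples(
        df["t_norm"].to_numpy(dtype=float), df["e_norm"].to_numpy(dtype=float)
    )


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table from CSV, validating the outcome columns."""
    df = pd.read_csv(path)
    for col in ("event", "time_years"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if (df["time_years"] <= 0).any():
        raise ParseError(f"{path}: nonpositive follow-up times")
    if "etiology" in df.columns:
        bad = set(df["etiology"].dropna().unique()) - ETIOLOGY_LABELS
        if bad:
            raise ParseError(f"{path}: unknown etiology labels {sorted(bad)}")
    for col in BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(int).astype(bool)
    return df


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table to CSV; booleans are coded 0/1."""
    out = table.copy()
    for col in BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def parameters_to_dict(params: PVParameters) -> dict:
    return {
        "stroke_work_j": params.stroke_work,
        "potential_energy_j": params.potential_energy,
        "ventricular_efficiency_pct": params.ventricular_efficiency,
        "external_power_w": params.external_power,
        "contractility_emax_mmhg_per_ml": params.contractility_emax,
        "energy_per_ejected_volume_j_per_ml": params.energy_per_ejected_volume,
        "arterial_elastance_mmhg_per_ml": params.arterial_elastance,
        "esp_mmhg": params.esp,
        "esv_ml": params.esv,
        "edv_ml": params.edv,
        "sv_ml": params.sv,
    }


def write_parameters_json(params: PVParameters, path: str | Path, extra: dict | None = None) -> None:
    payload = parameters_to_dict(params)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
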