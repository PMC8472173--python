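"""Delimited-text readers and writers for the pipeline's flat-file handoff.

All tables are UTF-8 CSV with a single header row whose column names encode
the units (``time_s``, ``compliance_kPa_inv``, ``temp_C`` ...).  Creep
curves are stored one file per specimen, named
``{variety}_{method}_{time}min_rep{i}.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .creep_model import CreepCurve, CreepFit
from .thermal_profiles import TemperatureProfile

__all__ = [
    "curve_filename",
    "write_creep_curve",
    "read_creep_curve",
    "write_profile",
    "read_profile",
    "fit_to_dict",
]


def curve_filename(variety: str, method: str, time_min: float, replicate: int) -> str:
    t = int(time_min) if float(time_min).is_integer() else time_min
    return f"{variety}_{method}_{t}min_rep{replicate}.csv"


def write_creep_curve(curve: CreepCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": curve.time,
            "compliance_kPa_inv": curve.compliance,
            "segment": curve.segment,
        }
    ).to_csv(path, index=False)


def read_creep_curve(path: str | Path, stress_kPa: float = 40.0) -> CreepCurve:
    """Read a (time_s, compliance_kPa_inv, segment) table; the unload time is
    the last loading sample."""
    df = pd.read_csv(path)
    required = {"time_s", "compliance_kPa_inv", "segment"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    loading = df["segment"] == "loading"
    if not loading.any():
        raise ValueError(f"{path}: no loading samples")
    return CreepCurve(
        time=df["time_s"].to_numpy(float),
        compliance=df["compliance_kPa_inv"].to_numpy(float),
        t_unload=float(df.loc[loading, "time_s"].max()),
        segment=df["segment"].to_numpy(),
        stress_kPa=stress_kPa,
    )


def write_profile(profile: TemperatureProfile, path: str | Path) -> None:
    pd.DataFrame({"time_s": profile.time, "temp_C": profile.temp}).to_csv(path, index=False)


def read_profile(path: str | Path) -> TemperatureProfile:
    df = pd.read_csv(path)
    return TemperatureProfile(time=df["time_s"].to_numpy(float), temp=df["temp_C"].to_numpy(float))


def fit_to_dict(fit: CreepFit) -> dict:
    """JSON-serializable report of one creep fit."""
    p = fit.params
    out = {
        "m": fit.m,
        "J0": p.J0,
        "JN": p.JN,
        "elements": [{"Ji": j, "RTi": r} for j, r in p.elements],
        "E_pct": fit.E_pct,
        "dw": fit.dw,
        "loss": fit.loss,
    }
    if fit.ci95 is not None:
        out["ci95"] = {k: list(v) for k, v in fit.ci95.items()}
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_coerce) + "\n")


def _coerce(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
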