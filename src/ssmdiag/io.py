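"""CSV and JSON interchange.

Univariate series CSV: columns ``t, y[, x_true]`` with empty cells for
missing observations.  Bear CSV: one row per bear-day with columns
``bear_id, t, y_u, y_v, s_u, s_v`` (empty = missing) plus optional
``c_true_u, c_true_v`` truth columns for simulated data.  Configuration
dataclasses round-trip through plain JSON objects.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bears import BearSeries
from .model import GaussianPrior, InvalidConfigError, SSMParams, TimeSeries

__all__ = [
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_bears_csv",
    "read_bears_csv",
    "config_to_json",
    "config_from_json",
]


def write_timeseries_csv(series: TimeSeries, path) -> None:
    data = {"t": np.arange(1, series.n + 1), "y": series.y}
    if series.x_true is not None:
        data["x_true"] = series.x_true
    pd.DataFrame(data).to_csv(path, index=False)


def read_timeseries_csv(path) -> TimeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if "y" not in df.columns:
        raise InvalidConfigError(f"{path}: missing required column 'y'")
    x_true = df["x_true"].to_numpy(float) if "x_true" in df.columns else None
    return TimeSeries(y=df["y"].to_numpy(float), x_true=x_true)


def write_bears_csv(bears: list, path, include_truth: bool = True) -> None:
    frames = []
    for b in bears:
        data = {
            "bear_id": b.bear_id,
            "t": np.arange(1, b.n_days + 1),
            "y_u": b.y[:, 0],
            "y_v": b.y[:, 1],
            "s_u": b.s[:, 0],
            "s_v": b.s[:, 1],
        }
        if include_truth and b.c_true is not None:
            data["c_true_u"] = b.c_true[:, 0]
            data["c_true_v"] = b.c_true[:, 1]
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_bears_csv(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"bear_id", "t", "y_u", "y_v", "s_u", "s_v"}
    if not required.issubset(df.columns):
        raise InvalidConfigError(f"{path}: missing columns {required - set(df.columns)}")
    bears = []
    for bear_id, grp in df.groupby("bear_id", sort=False):
        grp = grp.sort_values("t")
        y = grp[["y_u", "y_v"]].to_numpy(float)
        s = grp[["s_u", "s_v"]].to_numpy(float)
        c_true = None
        if {"c_true_u", "c_true_v"}.issubset(grp.columns):
            c = grp[["c_true_u", "c_true_v"]].to_numpy(float)
            if not np.isnan(c).all():
                c_true = c
        bears.append(BearSeries(bear_id=str(bear_id), y=y, s=s, c_true=c_true))
    return bears


def config_to_json(config, path=None) -> str:
    """Serialize a configuration dataclass (SSMParams, BearSimConfig,
    StudyConfig, ...) to JSON; optionally write it to ``path``."""
    d = dataclasses.asdict(config)
    d["__type__"] = type(config).__name__
    text = json.dumps(d, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def config_from_json(cls, source) -> object:
    """Rebuild a configuration dataclass from JSON text or a file path."""
    text = str(source)
    if not text.lstrip().startswith("{"):
        text = Path(source).read_text()
    d = json.loads(text)
    d.pop("__type__", None)
    if cls is SSMParams and isinstance(d.get("x0_prior"), dict):
        d["x0_prior"] = GaussianPrior(**d["x0_prior"])
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - field_names
    if unknown:
        raise InvalidConfigError(f"unknown fields for {cls.__name__}: {sorted(unknown)}")
    if isinstance(d.get("sigma_eta_grid"), list):
        d["sigma_eta_grid"] = tuple(d["sigma_eta_grid"])
    return cls(**d)
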