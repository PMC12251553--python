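"""Schema-validated CSV/JSON/YAML readers and writers.

Trajectory CSVs carry unit-suffixed headers (feed rates in L/min on disk,
L/h in memory); soft-sensor models persist to JSON together with their
normalization statistics and a fingerprint of them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Trajectory, lpm_to_lph
from .preprocessing import NormalizationStats
from .network import NetworkParams
from .soft_sensor import FEATURE_NAMES, SoftSensorDataset, SoftSensorRegressor, TARGET_NAMES

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_dataset_csv",
    "write_dataset_csv",
    "save_model",
    "load_model",
    "write_report_json",
    "load_yaml_config",
]

TRAJECTORY_COLUMNS = (
    "t_h", "X_gL", "S_gL", "E_UmL", "CL", "H_molL", "V_L",
    "fC_Lmin", "fN_Lmin", "fM_Lmin", "fA_Lmin",
    "Tw_C", "Sa_rpm", "Fa_Lmin",
)
_STATE_COLS = ("X_gL", "S_gL", "E_UmL", "CL", "H_molL", "V_L")
_FEED_COLS = ("fC_Lmin", "fN_Lmin", "fM_Lmin", "fA_Lmin")
_ENV_COLS = ("Tw_C", "Sa_rpm", "Fa_Lmin")


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame({
        "t_h": traj.t,
        **{c: traj.states[:, i] for i, c in enumerate(_STATE_COLS)},
        **{c: traj.feeds[:, i] / 60.0 for i, c in enumerate(_FEED_COLS)},  # L/h -> L/min
        **{c: traj.env[:, i] for i, c in enumerate(_ENV_COLS)},
    })


def frame_to_trajectory(df: pd.DataFrame, path="<frame>") -> Trajectory:
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    t = df["t_h"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: time column t_h must be strictly increasing")
    return Trajectory(
        t=t,
        states=df[list(_STATE_COLS)].to_numpy(dtype=float),
        feeds=lpm_to_lph(df[list(_FEED_COLS)].to_numpy(dtype=float)),
        env=df[list(_ENV_COLS)].to_numpy(dtype=float),
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(path) -> Trajectory:
    return frame_to_trajectory(pd.read_csv(path), path=path)


def write_dataset_csv(ds: SoftSensorDataset, path) -> None:
    df = pd.DataFrame({"t_h": ds.t})
    for c in ds.X.columns:
        df[c] = ds.X[c].to_numpy()
    if ds.y is not None:
        for j, name in enumerate(("x1_gL", "x2_gL", "x3_UmL")):
            df[name] = ds.y[:, j]
    if ds.split is not None:
        df["split"] = ds.split
    df.to_csv(path, index=False, float_format="%.12g")


def read_dataset_csv(path) -> SoftSensorDataset:
    df = pd.read_csv(path)
    _require_columns(df, ("t_h",) + FEATURE_NAMES, path)
    target_cols = ("x1_gL", "x2_gL", "x3_UmL")
    y = df[list(target_cols)].to_numpy(dtype=float) if all(c in df.columns for c in target_cols) else None
    feature_cols = [c for c in df.columns if c in FEATURE_NAMES + ("x6_dot",)]
    split = df["split"].to_numpy() if "split" in df.columns else None
    return SoftSensorDataset(t=df["t_h"].to_numpy(dtype=float), X=df[feature_cols].copy(), y=y, split=split)


def save_model(model: SoftSensorRegressor, path) -> None:
    """Persist a fitted soft sensor (architecture, weights, normalization
    stats, training config, seed) as JSON."""
    payload = {
        "format": "fermsense-soft-sensor",
        "version": 1,
        "params": model.get_params(),
        "feature_names": list(model.feature_names_in_),
        "n_features_in": model.n_features_in_,
        "x_stats": model.x_stats_.to_dict(),
        "y_stats": model.y_stats_.to_dict(),
        "stats_fingerprint": model.stats_fingerprint(),
        "networks": [
            {"weights": [W.tolist() for W in net.weights], "biases": [b.tolist() for b in net.biases]}
            for net in model.networks_
        ],
        "buffer": {"X": model._buffer_X.tolist(), "y": model._buffer_y.tolist()},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> SoftSensorRegressor:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "fermsense-soft-sensor":
        raise SchemaError(f"{path}: not a soft-sensor model file")
    model = SoftSensorRegressor(**payload["params"])
    model.feature_names_in_ = tuple(payload["feature_names"])
    model.n_features_in_ = payload["n_features_in"]
    model.x_stats_ = NormalizationStats.from_dict(payload["x_stats"])
    model.y_stats_ = NormalizationStats.from_dict(payload["y_stats"])
    model.networks_ = [
        NetworkParams([np.array(W) for W in net["weights"]], [np.array(b) for b in net["biases"]])
        for net in payload["networks"]
    ]
    model.loss_histories_ = [[], [], []]
    model._buffer_X = np.array(payload["buffer"]["X"], dtype=float)
    model._buffer_y = np.array(payload["buffer"]["y"], dtype=float)
    if payload["stats_fingerprint"] != model.stats_fingerprint():
        raise SchemaError(f"{path}: normalization statistics fingerprint mismatch")
    return model


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def load_yaml_config(path, allowed_keys=None) -> dict:
    """Load a YAML config mapping; unknown top-level keys are rejected when
    ``allowed_keys`` is given."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = sorted(set(cfg) - set(allowed_keys))
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {', '.join(unknown)}")
    return cfg
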