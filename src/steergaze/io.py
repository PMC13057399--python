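"""CSV readers/writers and run configuration.

CSV is the interchange format: UTF-8, mandatory header row, '.' decimal
separator, timestamps in seconds as floats from session start. A session
directory holds::

    session/
      schedule.csv   # one row per trial: order_index, radius, direction, density, seed
      road.csv       # one row per vertex: trial_id, x, y, cum_arclength, segment_label, signed_curvature
      trace.csv      # trial_id, t, head_x, head_y, heading, wheel_angle
      gaze_left.csv, gaze_right.csv   # t, eye, dir_x, dir_y, dir_z, confidence
      head.csv       # t, qx, qy, qz, qw, pos_x, pos_y, pos_z
      perimetry/*.csv                 # test_id, eye, azimuth_deg, elevation_deg, sensitivity_db
      truth/*.csv
      meta.yaml      # seeds, config and config hash
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .road_geometry import ChainedRoad, TrialSchedule, TurnSpec

TRACE_COLUMNS = ["trial_id", "t", "head_x", "head_y", "heading", "wheel_angle"]
GAZE_COLUMNS = ["t", "eye", "dir_x", "dir_y", "dir_z", "confidence"]
HEAD_COLUMNS = ["t", "qx", "qy", "qz", "qw", "pos_x", "pos_y", "pos_z"]
PERIMETRY_COLUMNS = ["test_id", "eye", "azimuth_deg", "elevation_deg", "sensitivity_db"]


@dataclass
class RunConfig:
    """Analysis configuration; defaults match the task's stated constants."""

    seed: int = 0
    vertex_spacing_m: float = 0.25
    window_fraction: float = 0.4
    confidence_threshold: float = 0.75
    saccade_threshold_policy: str = "adaptive"  # "adaptive" or "fixed"
    fixed_threshold_deg_s: float = 25.0
    min_saccade_duration_s: float = 0.025
    outlier_k: float = 3.0
    blind_criterion_db: float = 10.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def write_trace(trace: pd.DataFrame, path) -> None:
    trace[TRACE_COLUMNS].to_csv(path, index=False, float_format="%.9g")


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    for tid, g in df.groupby("trial_id"):
        dt = np.diff(g["t"].to_numpy())
        if (dt <= 0).any():
            row = int(g.index[np.argmax(dt <= 0)]) + 2  # 1-based incl. header
            raise ValueError(f"{path}: non-monotone timestamps in trial {tid} near line {row}")
    return df


def write_gaze(gaze: pd.DataFrame, path) -> None:
    gaze[GAZE_COLUMNS].to_csv(path, index=False, float_format="%.9g")


def read_gaze(path, norm_tol: float = 1e-3) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, GAZE_COLUMNS, path)
    dirs = df[["dir_x", "dir_y", "dir_z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(dirs, axis=1)
    valid = ~np.isnan(norms)
    bad = valid & (np.abs(norms - 1.0) > norm_tol)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: non-unit gaze vector near line {row}")
    if (np.diff(df["t"].to_numpy()) <= 0).any():
        raise ValueError(f"{path}: non-monotone timestamps")
    return df


def write_head(head: pd.DataFrame, path) -> None:
    head[HEAD_COLUMNS].to_csv(path, index=False, float_format="%.9g")


def read_head(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, HEAD_COLUMNS, path)
    return df


def write_perimetry(grid: pd.DataFrame, path) -> None:
    grid[PERIMETRY_COLUMNS].to_csv(path, index=False, float_format="%.9g")


def read_perimetry(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PERIMETRY_COLUMNS, path)
    return df


def write_schedule(schedule: TrialSchedule, path) -> None:
    rows = [
        {
            "order_index": i,
            "radius": spec.radius_m,
            "direction": spec.direction,
            "density": spec.flow_density,
            "seed": schedule.seed,
        }
        for i, spec in enumerate(schedule)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_schedule(path) -> TrialSchedule:
    df = pd.read_csv(path)
    _require_columns(df, ["order_index", "radius", "direction", "density", "seed"], path)
    df = df.sort_values("order_index")
    trials = tuple(
        TurnSpec(float(r.radius), str(r.direction), str(r.density))
        for r in df.itertuples()
    )
    return TrialSchedule(trials=trials, seed=int(df["seed"].iloc[0]))


def write_road(chain: ChainedRoad, path) -> None:
    frames = []
    for k, poly in enumerate(chain.polylines):
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": k,
                    "x": poly.vertices[:, 0],
                    "y": poly.vertices[:, 1],
                    "cum_arclength": poly.cum_arclength + chain.trial_offsets_m[k],
                    "segment_label": poly.segment_label,
                    "signed_curvature": poly.signed_curvature,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def write_meta(path, config: RunConfig, **extra) -> None:
    meta = {"config": asdict(config), "config_hash": config.hash(), **extra}
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_meta(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
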