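"""Binocular gaze processing: confidence gating, cyclopean merge, world-frame
azimuth/elevation, velocity filtering and saccade detection.

The chain mirrors how head-mounted eye trackers are processed for driving
tasks. Two asynchronous 120 Hz per-eye streams of unit gaze directions in the
head frame are gated on tracker confidence (samples below 0.75 become nulls),
interleaved on the union of timestamps (240 Hz effective) and averaged into a
cyclopean direction, rotated into the world with the head's orientation
(translation ignored), and expressed as azimuth/elevation relative to the
body-forward direction and the flat ground plane captured at session start.

Saccades are detected from the directionless gaze speed

    gamma_dot = sqrt(az_dot**2 + el_dot**2)

after rolling mean and rolling median filters (kernel 5 each) on the
component rates. Runs of samples above a per-participant speed threshold that
last at least 25 ms count as saccades. The threshold adapts to the
participant's velocity noise floor and is clamped to [15, 60] deg/s; typical
values sit near 25 deg/s.

Nulls (NaN) are never replaced with fabricated values: a null sample stays
null through every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

EYE_RATE_HZ = 120.0
#: Temporal pairing window for the cyclopean merge: half an eye frame.
MERGE_TOL_S = 0.5 / EYE_RATE_HZ
CONFIDENCE_THRESHOLD = 0.75
FILTER_KERNEL = 5
MIN_SACCADE_DURATION_S = 0.025
THRESHOLD_FLOOR_DEG_S = 15.0
THRESHOLD_CEIL_DEG_S = 60.0
#: Multiplier on the upper-quantile noise-floor speed; calibrated so the
#: default synthetic participant lands near 25 deg/s.
THRESHOLD_K = 1.3
THRESHOLD_QUANTILE = 0.95

BODY_FORWARD = np.array([0.0, 1.0, 0.0])
GROUND_NORMAL = np.array([0.0, 0.0, 1.0])

_DIR_COLS = ["dir_x", "dir_y", "dir_z"]


@dataclass(frozen=True)
class SaccadeEvent:
    onset_s: float
    offset_s: float
    peak_speed: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class TrialGazeSummary:
    """Middle-window gaze statistics for one trial.

    ``mean_azimuth_deg`` is computed after negating azimuth on left turns, so
    that looking into the bend is positive on both turn directions (gaze
    azimuth magnitude).
    """

    mean_azimuth_deg: float
    mean_elevation_deg: float
    saccade_count: int
    condition: tuple | None = None
    valid: bool = True


def gate_confidence(samples: pd.DataFrame, threshold: float = CONFIDENCE_THRESHOLD) -> pd.DataFrame:
    """Null out gaze directions with confidence strictly below ``threshold``."""
    conf = samples["confidence"].to_numpy(dtype=float)
    if np.nanmin(conf) < 0 or np.nanmax(conf) > 1:
        raise ValueError("confidence values must lie in [0, 1]")
    out = samples.copy()
    out.loc[conf < threshold, _DIR_COLS] = np.nan
    return out


def _nearest_valid(t_eye: np.ndarray, dirs: np.ndarray, t_out: np.ndarray, tol: float):
    """Nearest sample of one eye for each output time, within ``tol`` seconds.

    Returns an (n_out, 3) array with NaN rows where no sample is close enough
    or the nearest sample is null.
    """
    out = np.full((len(t_out), 3), np.nan)
    if len(t_eye) == 0:
        return out
    pos = np.searchsorted(t_eye, t_out)
    lo = np.clip(pos - 1, 0, len(t_eye) - 1)
    hi = np.clip(pos, 0, len(t_eye) - 1)
    d_lo = np.abs(t_out - t_eye[lo])
    d_hi = np.abs(t_out - t_eye[hi])
    idx = np.where(d_lo <= d_hi, lo, hi)
    dt = np.minimum(d_lo, d_hi)
    ok = dt <= tol + 1e-12
    out[ok] = dirs[idx[ok]]
    return out


def merge_cyclopean(
    left: pd.DataFrame,
    right: pd.DataFrame,
    tol_s: float = MERGE_TOL_S,
) -> pd.DataFrame:
    """Null-aware cyclopean merge of the two per-eye streams.

    Output timestamps are the union of both eyes' timestamps (240 Hz
    effective). At each output time the temporally nearest valid sample of
    each eye within ``tol_s`` contributes; the mean vector is renormalized.
    Both eyes null -> null.
    """
    t_l = left["t"].to_numpy(dtype=float)
    t_r = right["t"].to_numpy(dtype=float)
    d_l = left[_DIR_COLS].to_numpy(dtype=float)
    d_r = right[_DIR_COLS].to_numpy(dtype=float)
    t_out = np.union1d(t_l, t_r)

    v_l = _nearest_valid(t_l, d_l, t_out, tol_s)
    v_r = _nearest_valid(t_r, d_r, t_out, tol_s)
    ok_l = ~np.isnan(v_l).any(axis=1)
    ok_r = ~np.isnan(v_r).any(axis=1)
    total = np.where(ok_l, 1, 0) + np.where(ok_r, 1, 0)
    summed = np.where(ok_l[:, None], v_l, 0.0) + np.where(ok_r[:, None], v_r, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        merged = summed / total[:, None]
        merged = merged / np.linalg.norm(merged, axis=1)[:, None]
    merged[total == 0] = np.nan
    out = pd.DataFrame(merged, columns=_DIR_COLS)
    out.insert(0, "t", t_out)
    return out


def _as_rotation(rotation) -> Rotation:
    if isinstance(rotation, Rotation):
        return rotation
    mats = np.asarray(rotation, dtype=float)
    if mats.shape[-2:] != (3, 3):
        raise ValueError("rotation must be a Rotation or (..., 3, 3) matrices")
    eye = np.eye(3)
    err = np.max(np.abs(mats @ np.swapaxes(mats, -1, -2) - eye))
    if err > 1e-6:
        raise ValueError("rotation matrices are not orthonormal")
    return Rotation.from_matrix(mats)


def to_world(dir_head: np.ndarray, rotation) -> np.ndarray:
    """Rotate eye-in-head directions into the world frame (translation ignored).

    ``rotation`` is a scipy ``Rotation`` (possibly a stack matching the
    samples) or an array of orthonormal matrices. Null samples propagate.
    """
    dir_head = np.atleast_2d(np.asarray(dir_head, dtype=float))
    rot = _as_rotation(rotation)
    valid = ~np.isnan(dir_head).any(axis=1)
    out = np.full_like(dir_head, np.nan)
    if valid.any():
        if rot.single:
            out[valid] = rot.apply(dir_head[valid])
        else:
            out[valid] = rot[valid].apply(dir_head[valid])
    return out


def upsample_head_orientation(head: pd.DataFrame, t_out: np.ndarray) -> Rotation:
    """Spherically interpolate head orientation to the gaze timestamps.

    ``head`` needs columns ``t`` and quaternion columns ``qx, qy, qz, qw``.
    Timestamps outside the head-pose span are clamped to the ends.
    """
    t = head["t"].to_numpy(dtype=float)
    rots = Rotation.from_quat(head[["qx", "qy", "qz", "qw"]].to_numpy(dtype=float))
    slerp = Slerp(t, rots)
    t_clamped = np.clip(np.asarray(t_out, dtype=float), t[0], t[-1])
    return slerp(t_clamped)


def az_el(
    dir_world: np.ndarray,
    body_forward: np.ndarray = BODY_FORWARD,
    ground_normal: np.ndarray = GROUND_NORMAL,
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuth/elevation (deg) of world-frame directions.

    Azimuth is the signed angle of the ground-plane projection from
    ``body_forward``, positive rightward; elevation is the angle above the
    ground plane. Gaze straight up (zero-length projection) yields null.
    """
    f = np.asarray(body_forward, dtype=float)
    u = np.asarray(ground_normal, dtype=float)
    f = f / np.linalg.norm(f)
    u = u / np.linalg.norm(u)
    if abs(np.dot(f, u)) > 1e-8:
        raise ValueError("body_forward must be perpendicular to ground_normal")
    r = np.cross(f, u)

    d = np.atleast_2d(np.asarray(dir_world, dtype=float))
    x = d @ r
    y = d @ f
    z = d @ u
    azimuth = np.degrees(np.arctan2(x, y))
    elevation = np.degrees(np.arcsin(np.clip(z, -1.0, 1.0)))
    azimuth = np.where(np.hypot(x, y) < 1e-9, np.nan, azimuth)
    return azimuth, elevation


def _null_preserving_roll(x: np.ndarray, kernel: int, stat: str) -> np.ndarray:
    """Centred rolling statistic, windows truncated at the edges, nulls kept null."""
    s = pd.Series(x)
    roll = s.rolling(kernel, center=True, min_periods=1)
    out = (roll.mean() if stat == "mean" else roll.median()).to_numpy()
    out[np.isnan(x)] = np.nan
    return out


def _component_rate(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Finite-difference rate: central where both neighbours are valid,
    one-sided otherwise; null where the sample itself is null."""
    n = len(x)
    d = np.full(n, np.nan)
    valid = ~np.isnan(x)
    prev_ok = np.zeros(n, dtype=bool)
    next_ok = np.zeros(n, dtype=bool)
    prev_ok[1:] = valid[:-1]
    next_ok[:-1] = valid[1:]

    central = valid & prev_ok & next_ok
    i = np.flatnonzero(central)
    d[i] = (x[i + 1] - x[i - 1]) / (t[i + 1] - t[i - 1])

    fwd = valid & ~central & next_ok
    i = np.flatnonzero(fwd)
    d[i] = (x[i + 1] - x[i]) / (t[i + 1] - t[i])

    bwd = valid & ~central & ~next_ok & prev_ok
    i = np.flatnonzero(bwd)
    d[i] = (x[i] - x[i - 1]) / (t[i] - t[i - 1])
    return d


def velocity_series(
    azimuth_deg: np.ndarray,
    elevation_deg: np.ndarray,
    t: np.ndarray,
    kernel: int = FILTER_KERNEL,
) -> pd.DataFrame:
    """Filtered component rates and directionless speed gamma_dot (deg/s).

    Component rates are finite differences, then a rolling mean and a rolling
    median (kernel 5 each, ~20 ms at 240 Hz). Fewer than 6 valid samples
    yields an empty frame.
    """
    az = np.asarray(azimuth_deg, dtype=float)
    el = np.asarray(elevation_deg, dtype=float)
    t = np.asarray(t, dtype=float)
    valid = ~np.isnan(az) & ~np.isnan(el)
    if valid.sum() < 6:
        return pd.DataFrame(columns=["t", "az_dot", "el_dot", "speed"])
    az_dot = _component_rate(az, t)
    el_dot = _component_rate(el, t)
    for stat in ("mean", "median"):
        az_dot = _null_preserving_roll(az_dot, kernel, stat)
        el_dot = _null_preserving_roll(el_dot, kernel, stat)
    return pd.DataFrame(
        {"t": t, "az_dot": az_dot, "el_dot": el_dot, "speed": np.hypot(az_dot, el_dot)}
    )


def adaptive_threshold(
    speed: np.ndarray,
    floor_range: tuple[float, float] = (THRESHOLD_FLOOR_DEG_S, THRESHOLD_CEIL_DEG_S),
    k: float = THRESHOLD_K,
    quantile: float = THRESHOLD_QUANTILE,
) -> float:
    """Per-participant saccade speed threshold from the velocity noise floor.

    threshold = clamp(k * upper-quantile of the speed distribution) to
    ``floor_range``. Deterministic given the series. The bulk of gaze speed
    samples are inter-saccadic, so the upper quantile tracks the noise floor
    rather than the (rare) saccadic peaks.
    """
    speed = np.asarray(speed, dtype=float)
    if not np.isfinite(speed).any():
        raise ValueError("speed series has no valid samples")
    q = float(np.nanquantile(speed, quantile))
    return float(np.clip(k * q, floor_range[0], floor_range[1]))


def detect_saccades(
    speed: np.ndarray,
    t: np.ndarray,
    threshold: float,
    min_duration_s: float = MIN_SACCADE_DURATION_S,
) -> list[SaccadeEvent]:
    """Maximal supra-threshold runs lasting at least ``min_duration_s``.

    Null samples break runs; so do sampling gaps longer than 3 nominal
    intervals (the stream is then treated as separate segments).
    """
    speed = np.asarray(speed, dtype=float)
    t = np.asarray(t, dtype=float)
    above = np.where(np.isnan(speed), False, speed > threshold)
    if len(t) > 1:
        nominal = np.median(np.diff(t))
        gap_after = np.zeros(len(t), dtype=bool)
        gap_after[:-1] = np.diff(t) > 3 * nominal
    else:
        gap_after = np.zeros(len(t), dtype=bool)

    events: list[SaccadeEvent] = []
    start = None
    for i in range(len(t)):
        if above[i] and start is None:
            start = i
        end_run = start is not None and (
            not above[i] or gap_after[i] or i == len(t) - 1
        )
        if end_run:
            j = i if (above[i] and (gap_after[i] or i == len(t) - 1)) else i - 1
            if t[j] - t[start] >= min_duration_s:
                events.append(
                    SaccadeEvent(
                        onset_s=float(t[start]),
                        offset_s=float(t[j]),
                        peak_speed=float(np.nanmax(speed[start : j + 1])),
                    )
                )
            start = None
    return events


def remove_outlier_trials(counts, k: float = 3.0):
    """Drop trials whose saccade count falls outside mean +/- k*SD (per participant).

    ``counts`` is a sequence or Series of per-trial counts for one
    participant. Returns a boolean retention mask aligned with the input.
    """
    arr = np.asarray(counts, dtype=float)
    if len(arr) < 3:
        raise ValueError("need at least 3 trials per participant")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    return np.abs(arr - mean) <= k * sd


def trial_gaze_summary(
    series: pd.DataFrame,
    window: tuple[float, float],
    turn_direction: str,
    saccade_events: list[SaccadeEvent] = (),
    condition: tuple | None = None,
) -> TrialGazeSummary:
    """Mean azimuth (left turns negated), mean elevation and saccade count
    over the analysis window.

    The window is in the series' own time axis relative to its first sample.
    An all-null window is flagged (``valid=False``) with NaN means.
    """
    lo, hi = window
    t0 = series["t"].iloc[0]
    t = series["t"].to_numpy() - t0
    sel = (t >= lo) & (t <= hi)
    az = series["azimuth_deg"].to_numpy(dtype=float)[sel]
    el = series["elevation_deg"].to_numpy(dtype=float)[sel]
    if turn_direction == "left":
        az = -az
    count = sum(1 for e in saccade_events if lo <= (e.onset_s - t0) <= hi)
    if not np.isfinite(az).any():
        return TrialGazeSummary(np.nan, np.nan, count, condition=condition, valid=False)
    return TrialGazeSummary(
        mean_azimuth_deg=float(np.nanmean(az)),
        mean_elevation_deg=float(np.nanmean(el)),
        saccade_count=count,
        condition=condition,
        valid=True,
    )
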