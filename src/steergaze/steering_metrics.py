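"""Lane-position series and per-trial steering statistics.

Lane position rho is the perpendicular distance from the driver's head to the
*inner* road edge (the edge the turn curves toward); it runs from 0 at the
inner edge to 4 m at the outer edge of the 4 m roadway, with 2 m marking the
centre line. d_center = rho - 2 is the signed offset from the centre line,
positive toward the outer edge.

Per-trial statistics (mean rho, maximum departure from centre, lane-position
SD) are averaged over the middle 40% of the trial's traversal time, the
portion in which the driver negotiates the central part of the bend. At the
task's fixed 19 m/s over a 140 m trial this window starts at ~2.2 s.

The per-participant flow sensitivity contrasts mean lane position between
optic-flow-density conditions:

    delta_rho = 0.5 * ((rho_l - rho_m) + (rho_l - rho_h))

where l, m, h index the low, medium and high density conditions. Positive
values mean the participant hugged the inner edge more (cut the corner) when
flow was dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .road_geometry import RoadPolyline, TurnSpec, inner_edge_side

STEERING_RATE_HZ = 90.0
OFF_ROAD_CORRUPT_M = 10.0


@dataclass(frozen=True)
class TrialSteeringSummary:
    """Middle-window steering statistics for one trial."""

    mean_rho_mid: float
    max_departure: float
    sd_rho: float
    condition: tuple | None = None


@dataclass(frozen=True)
class FlowSensitivity:
    """Per-participant lane-position contrast across flow-density levels."""

    rho_l: float
    rho_m: float
    rho_h: float

    @property
    def delta_rho(self) -> float:
        return 0.5 * ((self.rho_l - self.rho_m) + (self.rho_l - self.rho_h))


def lane_position_series(
    trace: pd.DataFrame,
    road: RoadPolyline,
    spec: TurnSpec | None = None,
    rate_hz: float = STEERING_RATE_HZ,
) -> pd.DataFrame:
    """Distance-to-inner-edge series for one trial, resampled to a uniform rate.

    For each head sample the nearest centre-line vertex is found; the lateral
    (tangent-orthogonal) component of the head offset at that vertex, signed
    by the side of the local tangent, is offset by the half-width to yield
    rho. The series is then linearly resampled to an exact uniform rate over
    the trial's time span.

    Parameters
    ----------
    trace : DataFrame with columns ``t``, ``head_x``, ``head_y`` (one trial).
    road : the trial's centre-line polyline.
    spec : the trial's turn; defaults to ``road.spec``.

    Returns
    -------
    DataFrame with columns ``t``, ``rho``, ``d_center``.
    """
    if spec is None:
        spec = road.spec
    if len(trace) == 0:
        raise ValueError("empty trace")
    pts = trace[["head_x", "head_y"]].to_numpy(dtype=float)
    t = trace["t"].to_numpy(dtype=float)

    tree = cKDTree(road.vertices)
    dist, idx = tree.query(pts)
    if np.min(dist) > OFF_ROAD_CORRUPT_M:
        raise ValueError(
            f"trace is entirely more than {OFF_ROAD_CORRUPT_M:g} m off-road; flagged corrupt"
        )
    headings = road.headings[idx]
    offset = pts - road.vertices[idx]
    # Positive = head left of the local tangent.
    lat_left = np.cos(headings) * offset[:, 1] - np.sin(headings) * offset[:, 0]

    if inner_edge_side(spec) == "left":
        rho = road.half_width_m - lat_left
    else:
        rho = road.half_width_m + lat_left
    d_center = rho - road.half_width_m

    n = int(np.floor((t[-1] - t[0]) * rate_hz)) + 1
    t_uniform = t[0] + np.arange(n) / rate_hz
    out = pd.DataFrame(
        {
            "t": t_uniform,
            "rho": np.interp(t_uniform, t, rho),
            "d_center": np.interp(t_uniform, t, d_center),
        }
    )
    if "trial_id" in trace.columns:
        out["trial_id"] = int(trace["trial_id"].iloc[0])
    return out


def analysis_window(trial_duration_s: float, fraction: float = 0.4) -> tuple[float, float]:
    """Central-``fraction`` time window of a trial: [(0.5-f/2)T, (0.5+f/2)T]."""
    if trial_duration_s <= 0:
        raise ValueError("trial duration must be positive")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    half = fraction / 2.0
    return ((0.5 - half) * trial_duration_s, (0.5 + half) * trial_duration_s)


def trial_summary(
    series: pd.DataFrame,
    window: tuple[float, float],
    condition: tuple | None = None,
) -> TrialSteeringSummary:
    """Mean rho, maximum |d_center| and SD of rho over the analysis window.

    The window is expressed in the series' own time axis (relative to trial
    start if the series starts at 0).
    """
    t0 = series["t"].iloc[0]
    t = series["t"].to_numpy() - t0
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 3:
        raise ValueError("analysis window contains fewer than 3 samples")
    rho = series["rho"].to_numpy()[sel]
    d_center = series["d_center"].to_numpy()[sel]
    return TrialSteeringSummary(
        mean_rho_mid=float(np.mean(rho)),
        max_departure=float(np.max(np.abs(d_center))),
        sd_rho=float(np.std(rho, ddof=1)),
        condition=condition,
    )


def flow_sensitivity(rho_l: float, rho_m: float, rho_h: float) -> FlowSensitivity:
    """Per-participant delta-rho from the three per-density mean lane positions."""
    for v in (rho_l, rho_m, rho_h):
        if v is None or not np.isfinite(v):
            raise ValueError("all three density-level means are required")
    return FlowSensitivity(rho_l=float(rho_l), rho_m=float(rho_m), rho_h=float(rho_h))


def average_trajectory(
    series_list: list[pd.DataFrame],
    value_col: str = "rho",
    ci: float = 0.95,
) -> pd.DataFrame:
    """Pointwise mean trajectory with t-distribution confidence bands.

    All series must share a common uniform time base.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 series")
    t0 = series_list[0]["t"].to_numpy() - series_list[0]["t"].iloc[0]
    values = []
    for s in series_list:
        ts = s["t"].to_numpy() - s["t"].iloc[0]
        if len(ts) != len(t0) or not np.allclose(ts, t0, atol=1e-9):
            raise ValueError("series do not share a common time base")
        values.append(s[value_col].to_numpy())
    arr = np.vstack(values)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    half = stats.t.ppf(0.5 + ci / 2.0, n - 1) * sd / np.sqrt(n)
    return pd.DataFrame(
        {"t": t0, "mean": mean, "ci_low": mean - half, "ci_high": mean + half, "n": n}
    )
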