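"""Synthetic steering traces, binocular gaze streams, head poses and
perimetry grids with the statistical structure the analysis pipeline assumes,
plus ground truth for recovery tests.

The generator is not a cognitive model. Its job is to emulate the study
conditions the analysis operates on: a driver at a fixed 19.0 m/s who cuts
corners by an amount that grows with optic-flow density (a lookahead
lane-offset tracker), gaze with small-amplitude optokinetic nystagmus plus
discrete injected saccades and confidence dropouts sampled by two
asynchronous 120 Hz eye cameras, a 90 Hz head-pose stream, and unilateral
blind-field perimetry grids with configurable central sparing. Every
component draws from child streams of a single root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import lfilter

from .road_geometry import (
    ChainedRoad,
    TrialSchedule,
    TurnSpec,
    chain_trials,
    HALF_WIDTH_M,
    left_normal,
    pose_at,
)

SPEED_MPS = 19.0
STEERING_RATE_HZ = 90.0
EYE_RATE_HZ = 120.0
HEAD_RATE_HZ = 90.0
_INTERNAL_RATE_HZ = 480.0


@dataclass
class DriverParams:
    """Lookahead lane-offset tracker parameters.

    ``cut_gain_by_density`` is the lateral bias toward the inner edge (m)
    inside arcs, per optic-flow density; corner cutting grows with density.
    ``steering_gain`` is the first-order tracking rate (1/s); ``lookahead_s``
    the anticipatory smoothing horizon. Motor noise is a smooth lateral
    perturbation with the given per-sample SD.
    """

    speed_mps: float = SPEED_MPS
    cut_gain_by_density: dict = field(
        default_factory=lambda: {"low": 0.15, "medium": 0.45, "high": 0.50}
    )
    steering_gain: float = 2.0
    lookahead_s: float = 1.0
    motor_noise_sd: float = 0.12
    timestamp_jitter_sd: float = 0.0005
    sample_rate_hz: float = STEERING_RATE_HZ

    def __post_init__(self) -> None:
        if self.speed_mps <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("speed and sample rate must be positive")
        if self.motor_noise_sd < 0 or self.timestamp_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for d, g in self.cut_gain_by_density.items():
            if abs(g) > 2.0:
                raise ValueError(f"cut gain for {d!r} outside [-2, 2] m")


@dataclass
class GazeParams:
    """Synthetic gaze signal parameters (free parameters of the generator;
    the study constrains only their qualitative structure).

    The latent azimuth points toward the inside of the upcoming bend with
    eccentricity ``ecc_gain_deg_m * curvature``; optokinetic nystagmus rides
    on top as a slow phase at ``nystagmus_slow_gain`` times the vehicle yaw
    rate with quick-phase resets of ``quick_phase_amp_deg`` executed at
    ``quick_phase_speed_deg_s`` (sub-threshold for the saccade detector, so
    only injected saccades are counted as ground truth).
    """

    nystagmus_slow_gain: float = 0.25
    quick_phase_amp_deg: float = 1.5
    quick_phase_speed_deg_s: float = 10.0
    saccade_rate_per_trial: int = 6
    saccade_amp_deg: float = 4.0
    saccade_duration_s: float = 0.040
    noise_floor_deg: float = 0.10
    dropout_prob: float = 0.02
    eye_rate_hz: float = EYE_RATE_HZ
    ecc_gain_deg_m: float = 400.0
    elevation_deg: float = -7.5
    head_gain: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.eye_rate_hz <= 0:
            raise ValueError("eye_rate_hz must be positive")


@dataclass
class GroundTruth:
    """What the generator actually put in, for recovery tests."""

    true_mean_lane_by_density: dict | None = None
    true_saccade_intervals: list | None = None
    true_mean_abs_azimuth_by_radius: dict | None = None
    true_deficit_area_deg2: float | None = None
    seed: int | None = None


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, rate_hz: float) -> np.ndarray:
    """Stationary smooth Gaussian noise with per-sample SD ``sd`` (0.1 s scale)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    sigma = 0.1 * rate_hz
    raw = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma, mode="reflect")
    # Gaussian smoothing of white noise reduces the SD by (2*sigma*sqrt(pi))^-1/2.
    return sd * raw * np.sqrt(2.0 * sigma * np.sqrt(np.pi))


def simulate_drive(
    schedule: TrialSchedule,
    params: DriverParams | None = None,
    seed: int = 0,
    chain: ChainedRoad | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one participant's steering trace over a trial schedule.

    The head follows the road centre line offset toward the inner edge by the
    density's cut gain inside arcs (zero on straights), smoothed over the
    lookahead horizon and tracked with a first-order lag, plus smooth lateral
    motor noise. Samples arrive at a nominal 90 Hz with optional timestamp
    jitter.

    Returns the trace DataFrame (``trial_id, t, head_x, head_y, heading,
    wheel_angle``) and the generator ground truth.
    """
    params = params or DriverParams()
    if chain is None:
        chain = chain_trials(schedule)
    rng_path, rng_time = np.random.default_rng(seed).spawn(2)

    speed = params.speed_mps
    rate = params.sample_rate_hz
    total = chain.total_length_m
    duration = total / speed
    n = int(np.floor(duration * rate))
    t = np.arange(n) / rate
    if params.timestamp_jitter_sd > 0:
        t = np.sort(t + rng_time.normal(0.0, params.timestamp_jitter_sd, n))
        t -= t[0]
    s = np.clip(speed * t, 0.0, total - 1e-9)
    trial_idx = chain.trial_index_at(s)
    s_local = s - chain.trial_offsets_m[trial_idx]

    # Target lateral offset (left-normal coordinates) per sample.
    gains = np.array(
        [params.cut_gain_by_density[spec.flow_density] for spec in schedule]
    )
    inner_sign = np.array([1.0 if spec.direction == "left" else -1.0 for spec in schedule])
    lead = np.array([spec.lead_straight_m for spec in schedule])
    arc_end = lead + np.array([spec.arc_length_m for spec in schedule])
    in_arc = (s_local > lead[trial_idx]) & (s_local < arc_end[trial_idx])
    target = np.where(in_arc, inner_sign[trial_idx] * gains[trial_idx], 0.0)

    # Anticipatory smoothing over the lookahead window, then first-order lag.
    w = max(1, int(round(params.lookahead_s * rate)))
    smoothed = uniform_filter1d(target, size=w, mode="nearest")
    dt = 1.0 / rate
    alpha = 1.0 - np.exp(-params.steering_gain * dt)
    tracked = lfilter([alpha], [1.0, alpha - 1.0], smoothed, zi=[0.0])[0]
    if np.max(np.abs(tracked)) >= HALF_WIDTH_M:
        raise ValueError("reference path leaves the roadway; reduce cut gains")

    offset = tracked + _smooth_noise(rng_path, n, params.motor_noise_sd, rate)

    x = np.empty(n)
    y = np.empty(n)
    h = np.empty(n)
    for k, poly in enumerate(chain.polylines):
        m = trial_idx == k
        if not m.any():
            continue
        cx, cy, ch = pose_at(poly.spec, poly.entry_pose, s_local[m])
        nrm = left_normal(ch)
        x[m] = cx + offset[m] * nrm[:, 0]
        y[m] = cy + offset[m] * nrm[:, 1]
        h[m] = ch
    # Head heading: path tangent corrected for lateral motion.
    d_offset = np.gradient(offset, s, edge_order=1)
    heading = h + np.arctan(d_offset)
    curv = np.array([spec.signed_curvature for spec in schedule])
    wheel = 100.0 * np.where(in_arc, curv[trial_idx], 0.0)

    trace = pd.DataFrame(
        {
            "trial_id": trial_idx.astype(int),
            "t": t,
            "head_x": x,
            "head_y": y,
            "heading": heading,
            "wheel_angle": wheel,
        }
    )
    truth = GroundTruth(
        true_mean_lane_by_density={
            d: HALF_WIDTH_M - g for d, g in params.cut_gain_by_density.items()
        },
        seed=seed,
    )
    return trace, truth


def _trial_start_times(trace: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Start time of each trial plus session end, from the trace."""
    starts = trace.groupby("trial_id")["t"].min().sort_index().to_numpy()
    return starts, float(trace["t"].iloc[-1])


def _nystagmus_sawtooth(
    v_slow: np.ndarray, du: float, amp: float, quick_speed: float
) -> np.ndarray:
    """Slow-phase drift with quick-phase resets once |drift| exceeds ``amp``."""
    out = np.empty_like(v_slow)
    drift = 0.0
    resetting = 0.0  # signed quick-phase velocity while resetting, else 0
    for i in range(len(v_slow)):
        if resetting:
            drift += resetting * du
            if drift * resetting >= 0.0:  # crossed zero
                drift, resetting = 0.0, 0.0
        else:
            drift += v_slow[i] * du
            if abs(drift) > amp:
                resetting = -np.sign(drift) * quick_speed
        out[i] = drift
    return out


def simulate_gaze(
    trace: pd.DataFrame,
    chain: ChainedRoad,
    params: GazeParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate binocular gaze and head orientation for a steering trace.

    Gaze is generated in the seated (lab) frame: body-forward is +y, the
    ground normal +z, and azimuth stays centred near zero as in recordings
    from a fixed driving seat. Returns (left eye, right eye, head, truth):
    per-eye frames ``t, eye, dir_x, dir_y, dir_z, confidence`` at 120 Hz each
    with a half-frame phase offset, and a 90 Hz head frame with quaternion
    and position columns.
    """
    params = params or GazeParams()
    rngs = np.random.default_rng(seed).spawn(4)
    rng_sacc, rng_noise_l, rng_noise_r, rng_conf = rngs

    starts, t_end = _trial_start_times(trace)
    t0 = float(trace["t"].iloc[0])
    specs = list(chain.schedule)
    n_trials = len(starts)
    bounds = np.append(starts, t_end)

    du = 1.0 / _INTERNAL_RATE_HZ
    u = np.arange(t0, t_end, du)
    trial_of_u = np.clip(np.searchsorted(bounds, u, side="right") - 1, 0, n_trials - 1)

    # Latent eccentricity toward the inside of the bend (left turn -> negative
    # azimuth) while within the arc, smoothed over ~1 s.
    speed = np.array(
        [specs[k].total_length_m / max(bounds[k + 1] - bounds[k], 1e-9) for k in range(n_trials)]
    )
    s_local = (u - bounds[trial_of_u]) * speed[trial_of_u]
    lead = np.array([sp.lead_straight_m for sp in specs])
    arc_end = lead + np.array([sp.arc_length_m for sp in specs])
    curv = np.array([sp.signed_curvature for sp in specs])
    in_arc = (s_local > lead[trial_of_u]) & (s_local < arc_end[trial_of_u])
    az_base = np.where(in_arc, -params.ecc_gain_deg_m * curv[trial_of_u], 0.0)
    az_base = uniform_filter1d(az_base, size=int(_INTERNAL_RATE_HZ), mode="nearest")

    # Optokinetic nystagmus: slow phase counter to the scene rotation.
    yaw_rate_deg = np.degrees(speed[trial_of_u] * curv[trial_of_u]) * in_arc
    if params.nystagmus_slow_gain > 0 and params.quick_phase_amp_deg > 0:
        nyst = _nystagmus_sawtooth(
            -params.nystagmus_slow_gain * yaw_rate_deg,
            du,
            params.quick_phase_amp_deg,
            params.quick_phase_speed_deg_s,
        )
    else:
        nyst = np.zeros_like(u)

    # Injected saccades with known intervals: alternating-direction smooth
    # steps placed in equal slots inside each trial.
    sacc = np.zeros_like(u)
    truth_intervals: list[list[tuple[float, float]]] = []
    dur = params.saccade_duration_s
    for k in range(n_trials):
        intervals = []
        n_sacc = params.saccade_rate_per_trial
        if n_sacc > 0:
            lo, hi = bounds[k] + 0.3, bounds[k + 1] - 0.3 - dur
            slot = (hi - lo) / n_sacc
            sign = 1.0 if k % 2 == 0 else -1.0
            for j in range(n_sacc):
                onset = lo + j * slot + rng_sacc.uniform(0.0, max(slot - dur - 0.05, 0.0))
                xph = np.clip((u - onset) / dur, 0.0, 1.0)
                step = 0.5 * (1.0 - np.cos(np.pi * xph))
                sacc += sign * params.saccade_amp_deg * step
                sign = -sign
                intervals.append((float(onset), float(onset + dur)))
        truth_intervals.append(intervals)

    az = az_base + nyst + sacc
    el = np.full_like(u, params.elevation_deg)
    head_az = params.head_gain * az_base

    def _eye_frame(eye: str, phase: float, rng_noise) -> pd.DataFrame:
        te = np.arange(t0 + phase, t_end, 1.0 / params.eye_rate_hz)
        az_e = np.interp(te, u, az) + rng_noise.normal(0.0, params.noise_floor_deg, len(te))
        el_e = np.interp(te, u, el) + rng_noise.normal(0.0, params.noise_floor_deg, len(te))
        h_az = np.interp(te, u, head_az)
        # World direction from azimuth (deg, + rightward) and elevation.
        az_r, el_r = np.radians(az_e), np.radians(el_e)
        d_world = np.column_stack(
            [np.sin(az_r) * np.cos(el_r), np.cos(az_r) * np.cos(el_r), np.sin(el_r)]
        )
        # Eye-in-head: undo the head yaw (positive azimuth = clockwise about +z).
        th = np.radians(h_az)
        cos_t, sin_t = np.cos(-th), np.sin(-th)
        dx, dy = d_world[:, 0], d_world[:, 1]
        eih = np.column_stack(
            [cos_t * dx + sin_t * dy, -sin_t * dx + cos_t * dy, d_world[:, 2]]
        )
        conf = np.clip(rng_conf.normal(0.95, 0.03, len(te)), 0.0, 1.0)
        drop = rng_conf.random(len(te)) < params.dropout_prob
        conf[drop] = rng_conf.uniform(0.0, 0.74, int(drop.sum()))
        return pd.DataFrame(
            {
                "t": te,
                "eye": eye,
                "dir_x": eih[:, 0],
                "dir_y": eih[:, 1],
                "dir_z": eih[:, 2],
                "confidence": conf,
            }
        )

    left = _eye_frame("left", 0.0, rng_noise_l)
    right = _eye_frame("right", 0.5 / params.eye_rate_hz, rng_noise_r)

    th = np.arange(t0, t_end, 1.0 / HEAD_RATE_HZ)
    yaw = np.radians(np.interp(th, u, head_az))
    head = pd.DataFrame(
        {
            "t": th,
            "qx": 0.0,
            "qy": 0.0,
            "qz": np.sin(-yaw / 2.0),
            "qw": np.cos(-yaw / 2.0),
            "pos_x": np.interp(th, trace["t"], trace["head_x"]),
            "pos_y": np.interp(th, trace["t"], trace["head_y"]),
            "pos_z": 1.2,
        }
    )

    radii = sorted({sp.radius_m for sp in specs})
    truth = GroundTruth(
        true_saccade_intervals=truth_intervals,
        true_mean_abs_azimuth_by_radius={r: params.ecc_gain_deg_m / r for r in radii},
        seed=seed,
    )
    return left, right, head, truth


# --- Perimetry -------------------------------------------------------------

_INTACT_DB = 30.0
_INTACT_SD_DB = 1.5
_BLIND_DB = 0.5
_BLIND_SD_DB = 0.5


def _test_points(pattern: str) -> tuple[np.ndarray, np.ndarray]:
    """Test-point lattice. Simplified rectangular versions of the clinical
    24-2 (6 deg spacing at 3 deg offsets, +/-27 x +/-21) and 10-2 (2 deg
    spacing at 1 deg offsets, central +/-9) patterns."""
    if pattern == "24-2":
        az = np.arange(-27.0, 28.0, 6.0)
        el = np.arange(-21.0, 22.0, 6.0)
    elif pattern == "10-2":
        az = np.arange(-9.0, 10.0, 2.0)
        el = np.arange(-9.0, 10.0, 2.0)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    mesh_az, mesh_el = np.meshgrid(az, el)
    return mesh_az.ravel(), mesh_el.ravel()


def simulate_perimetry(
    side: str,
    sparing_radius_deg: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Monocular 24-2 and 10-2 grids for both eyes with a unilateral deficit.

    One hemifield (``side``) is set below the blindness criterion except for
    a central disk of ``sparing_radius_deg``; small independent noise is
    drawn per eye and per test.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if sparing_radius_deg < 0:
        raise ValueError("sparing radius must be non-negative")
    rng = np.random.default_rng(seed)
    grids: dict[str, pd.DataFrame] = {}
    for eye in ("od", "os"):
        for pattern in ("24-2", "10-2"):
            az, el = _test_points(pattern)
            blind = (az < 0) if side == "left" else (az > 0)
            blind &= np.hypot(az, el) > sparing_radius_deg
            sens = rng.normal(_INTACT_DB, _INTACT_SD_DB, len(az))
            sens[blind] = np.clip(
                rng.normal(_BLIND_DB, _BLIND_SD_DB, int(blind.sum())), 0.0, None
            )
            grids[f"{eye}_{pattern.replace('-', '')}"] = pd.DataFrame(
                {
                    "test_id": pattern,
                    "eye": eye,
                    "azimuth_deg": az,
                    "elevation_deg": el,
                    "sensitivity_db": sens,
                }
            )
    half_area = 0.5 * (2 * 27.0) * (2 * 21.0)
    sparing_area = 0.5 * np.pi * min(sparing_radius_deg, 21.0) ** 2
    truth = GroundTruth(
        true_deficit_area_deg2=half_area - sparing_area, seed=seed
    )
    return grids, truth


def simulate_cohort_cells(
    n_per_group: int = 10,
    groups: tuple[str, ...] = ("control", "leftCB", "rightCB"),
    group_effects: dict | None = None,
    density_effects: dict | None = None,
    subject_sd: float = 0.25,
    cell_sd: float = 0.15,
    baseline: float = 1.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Condition-cell means for a synthetic cohort (mean lane position, m).

    Each subject gets a random intercept (SD ``subject_sd``); each of the 18
    direction x radius x density cells gets independent noise (SD
    ``cell_sd``) plus optional additive group and density effects. This is
    the scale at which the group-level ANOVA operates; it bypasses per-sample
    simulation.
    """
    from itertools import product

    rng = np.random.default_rng(seed)
    group_effects = group_effects or {}
    density_effects = density_effects or {}
    rows = []
    pid = 0
    for g in groups:
        for _ in range(n_per_group):
            pid += 1
            intercept = rng.normal(0.0, subject_sd)
            for d, r, dens in product(("left", "right"), (35.0, 55.0, 75.0),
                                      ("low", "medium", "high")):
                value = (
                    baseline
                    + intercept
                    + group_effects.get(g, 0.0)
                    + density_effects.get(dens, 0.0)
                    + rng.normal(0.0, cell_sd)
                )
                rows.append(
                    {
                        "participant_id": f"P{pid:03d}",
                        "group": g,
                        "direction": d,
                        "radius": r,
                        "density": dens,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
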