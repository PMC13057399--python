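"""Procedural roadway geometry for a fixed-speed curve-negotiation task.

The roadway is a seamless chain of self-similar trials. Each trial consists of
a 20 m straight lead-in, a 100 m bend of constant curvature (radius 35, 55 or
75 m, turning left or right), and a 20 m straight tail, for a total of 140 m.
The road is 4 m wide (half-width 2 m). A session is a shuffled schedule of 144
trials: 8 repeats of each cell of the 3 (radius) x 2 (direction) x 3 (optic
flow density) factorial.

Coordinates are plan-view, right-handed: x east, y north, heading measured
counterclockwise from +x. A left turn has positive signed curvature
(counterclockwise in plan view). The first trial starts at the origin heading
+y, matching the body-forward reference of the gaze module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

RADII_M = (35.0, 55.0, 75.0)
DIRECTIONS = ("left", "right")
DENSITIES = ("low", "medium", "high")
ARC_LENGTH_M = 100.0
STRAIGHT_LENGTH_M = 20.0
HALF_WIDTH_M = 2.0
TRIAL_LENGTH_M = 2 * STRAIGHT_LENGTH_M + ARC_LENGTH_M
N_TRIALS = 144
N_REPEATS = 8
DEFAULT_VERTEX_SPACING_M = 0.25


@dataclass(frozen=True)
class Pose:
    """Planar position plus heading (rad, CCW from +x)."""

    x: float
    y: float
    heading_rad: float

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


#: Entry pose of the first trial: origin, heading +y.
ORIGIN_POSE = Pose(0.0, 0.0, np.pi / 2)


@dataclass(frozen=True)
class TurnSpec:
    """One trial's turn: radius, direction and optic-flow density label.

    Densities are carried as metadata only; they parameterize the scene
    texture in the task, not the geometry.
    """

    radius_m: float
    direction: str
    flow_density: str
    arc_length_m: float = ARC_LENGTH_M
    lead_straight_m: float = STRAIGHT_LENGTH_M
    tail_straight_m: float = STRAIGHT_LENGTH_M

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.flow_density not in DENSITIES:
            raise ValueError(f"flow_density must be one of {DENSITIES}, got {self.flow_density!r}")
        for name in ("radius_m", "arc_length_m", "lead_straight_m", "tail_straight_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def signed_curvature(self) -> float:
        """+1/radius for left turns, -1/radius for right turns."""
        sign = 1.0 if self.direction == "left" else -1.0
        return sign / self.radius_m

    @property
    def total_length_m(self) -> float:
        return self.lead_straight_m + self.arc_length_m + self.tail_straight_m

    @property
    def condition(self) -> tuple[float, str, str]:
        return (self.radius_m, self.direction, self.flow_density)


def inner_edge_side(spec: TurnSpec) -> str:
    """Side of the road edge the turn curves toward: left turns -> "left"."""
    return spec.direction


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered sequence of trials plus the seed that shuffled it."""

    trials: tuple[TurnSpec, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]


def build_schedule(seed: int) -> TrialSchedule:
    """Uniformly shuffled 144-trial schedule: 8 repeats of the 18-cell factorial.

    Reproducible per seed (numpy ``default_rng``).
    """
    pool = [
        TurnSpec(r, d, dens)
        for r, d, dens in product(RADII_M, DIRECTIONS, DENSITIES)
    ] * N_REPEATS
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    return TrialSchedule(trials=tuple(pool[i] for i in order), seed=int(seed))


def pose_at(spec: TurnSpec, entry: Pose, s) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form pose (x, y, heading) at arc length ``s`` along one trial.

    ``s`` may be a scalar or array in [0, total_length]. The trial is the
    lead straight, a circular arc of signed curvature k (left positive, so
    the centre sits on the left-normal side), then the tail straight.
    """
    s = np.asarray(s, dtype=float)
    k = spec.signed_curvature
    h0 = entry.heading_rad
    L0 = spec.lead_straight_m
    L1 = L0 + spec.arc_length_m

    # Arc geometry: start point and centre.
    p1 = entry.xy + L0 * np.array([np.cos(h0), np.sin(h0)])
    center = p1 + (1.0 / k) * np.array([-np.sin(h0), np.cos(h0)])
    h_exit = h0 + k * spec.arc_length_m
    p2 = center + (1.0 / k) * np.array([np.sin(h_exit), -np.cos(h_exit)])

    s_arc = np.clip(s, L0, L1) - L0
    h = np.where(s <= L0, h0, np.where(s >= L1, h_exit, h0 + k * s_arc))

    x = np.empty_like(s)
    y = np.empty_like(s)
    lead = s <= L0
    tail = s >= L1
    arc = ~lead & ~tail

    x[lead] = entry.x + s[lead] * np.cos(h0)
    y[lead] = entry.y + s[lead] * np.sin(h0)
    h_a = h0 + k * s_arc[arc]
    x[arc] = center[0] + (1.0 / k) * np.sin(h_a)
    y[arc] = center[1] - (1.0 / k) * np.cos(h_a)
    x[tail] = p2[0] + (s[tail] - L1) * np.cos(h_exit)
    y[tail] = p2[1] + (s[tail] - L1) * np.sin(h_exit)
    return x, y, h


def left_normal(heading_rad) -> np.ndarray:
    """Unit normal pointing to the left of the local tangent, shape (..., 2)."""
    heading_rad = np.asarray(heading_rad, dtype=float)
    return np.stack([-np.sin(heading_rad), np.cos(heading_rad)], axis=-1)


@dataclass
class RoadPolyline:
    """Discretized centre line of one trial.

    ``vertices`` are planar points at uniform arc-length spacing;
    ``signed_curvature`` is 0 on straights and +/-1/radius on the arc;
    ``headings`` hold the exact tangent heading at each vertex.
    """

    vertices: np.ndarray
    cum_arclength: np.ndarray
    segment_label: np.ndarray
    signed_curvature: np.ndarray
    headings: np.ndarray
    entry_pose: Pose
    exit_pose: Pose
    spec: TurnSpec
    half_width_m: float = HALF_WIDTH_M

    @property
    def total_length_m(self) -> float:
        return float(self.cum_arclength[-1])

    def __len__(self) -> int:
        return len(self.cum_arclength)


def build_trial_polyline(
    spec: TurnSpec,
    entry_pose: Pose = ORIGIN_POSE,
    vertex_spacing_m: float = DEFAULT_VERTEX_SPACING_M,
) -> RoadPolyline:
    """Discretize one trial at uniform arc-length spacing.

    Spacing is capped at 1 m; the default 0.25 m keeps the chord-sagitta
    error below 0.3 mm even at radius 35 m.
    """
    if not (0.0 < vertex_spacing_m <= 1.0):
        raise ValueError("vertex_spacing_m must be in (0, 1] m")
    total = spec.total_length_m
    n_seg = int(round(total / vertex_spacing_m))
    s = np.linspace(0.0, total, n_seg + 1)
    x, y, h = pose_at(spec, entry_pose, s)
    L0 = spec.lead_straight_m
    L1 = L0 + spec.arc_length_m
    on_arc = (s > L0) & (s < L1)
    labels = np.where(on_arc, "arc", "straight")
    curvature = np.where(on_arc, spec.signed_curvature, 0.0)
    return RoadPolyline(
        vertices=np.column_stack([x, y]),
        cum_arclength=s,
        segment_label=labels,
        signed_curvature=curvature,
        headings=h,
        entry_pose=entry_pose,
        exit_pose=Pose(float(x[-1]), float(y[-1]), float(h[-1])),
        spec=spec,
    )


@dataclass
class ChainedRoad:
    """Seamless chain of trial polylines sharing poses at the junctions.

    ``window(k)`` exposes the current trial plus the two upcoming ones, as
    the task keeps two turns ahead in the scene and drops passed turns.
    """

    schedule: TrialSchedule
    polylines: list[RoadPolyline]
    vertex_spacing_m: float
    trial_offsets_m: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lengths = [p.total_length_m for p in self.polylines]
        self.trial_offsets_m = np.concatenate([[0.0], np.cumsum(lengths)])

    @property
    def total_length_m(self) -> float:
        return float(self.trial_offsets_m[-1])

    def __len__(self) -> int:
        return len(self.polylines)

    def window(self, k: int) -> list[RoadPolyline]:
        """Trials visible while driving trial ``k``: k, k+1, k+2."""
        if not 0 <= k < len(self.polylines):
            raise IndexError(f"trial index {k} out of range")
        return self.polylines[k : k + 3]

    def trial_index_at(self, s_global) -> np.ndarray:
        """Trial index for global arc length(s), clipped to the last trial."""
        idx = np.searchsorted(self.trial_offsets_m, s_global, side="right") - 1
        return np.clip(idx, 0, len(self.polylines) - 1)


def chain_trials(
    schedule: TrialSchedule,
    vertex_spacing_m: float = DEFAULT_VERTEX_SPACING_M,
) -> ChainedRoad:
    """Build the continuous road: each trial starts at the previous exit pose."""
    polylines: list[RoadPolyline] = []
    pose = ORIGIN_POSE
    for spec in schedule:
        poly = build_trial_polyline(spec, pose, vertex_spacing_m)
        polylines.append(poly)
        pose = poly.exit_pose
    return ChainedRoad(schedule=schedule, polylines=polylines, vertex_spacing_m=vertex_spacing_m)
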