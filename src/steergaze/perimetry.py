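"""Composite visual-field maps and deficit metrics from Humphrey-style grids.

Monocular sensitivity maps from 24-2 (6 deg spacing, +/-27 x +/-21 deg extent)
and 10-2 (2 deg spacing, central +/-9 deg) perimetry are interpolated onto a
common regular grid spanning 27 deg horizontally and 21 deg vertically and
averaged cellwise across the four inputs (two tests x two eyes); the 10-2
tests contribute only centrally. Deficit areas are area-weighted sums of
blind cells (sensitivity below a configurable dB criterion) per hemifield and
per upper/lower field, in squared degrees with solid-angle (cos-elevation)
cell weights. Sparing is the intact fraction of a central region: a 10 deg
radius disk, or the central 24 deg square extent clipped to the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy import stats

AZ_EXTENT_DEG = 27.0
EL_EXTENT_DEG = 21.0
DEFAULT_GRID_STEP_DEG = 1.0
DEFAULT_BLIND_CRITERION_DB = 10.0


@dataclass
class PerimetryGrid:
    """Regular visual-field map: sensitivity[el, az] on cell centres."""

    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray
    sensitivity: np.ndarray
    provenance: str = "composite"

    @property
    def step_deg(self) -> float:
        return float(self.azimuth_deg[1] - self.azimuth_deg[0])

    def cell_areas_deg2(self) -> np.ndarray:
        """Solid-angle cell weights in squared degrees: step^2 * cos(elevation)."""
        step = self.step_deg
        return np.broadcast_to(
            (step * step * np.cos(np.radians(self.elevation_deg)))[:, None],
            self.sensitivity.shape,
        )


@dataclass(frozen=True)
class DeficitMetrics:
    total_deficit_deg2: float
    left_deficit_deg2: float
    right_deficit_deg2: float
    upper_deficit_deg2: float
    lower_deficit_deg2: float
    sparing_central10: float
    sparing_central24: float


def _grid_centres(step: float) -> tuple[np.ndarray, np.ndarray]:
    az = np.arange(-AZ_EXTENT_DEG + step / 2, AZ_EXTENT_DEG, step)
    el = np.arange(-EL_EXTENT_DEG + step / 2, EL_EXTENT_DEG, step)
    return az, el


def _interp_map(
    grid_df: pd.DataFrame,
    az: np.ndarray,
    el: np.ndarray,
    extrapolate_nearest: bool,
) -> np.ndarray:
    """Interpolate one monocular test onto the common grid.

    Piecewise linear on the test-point triangulation; 24-2 inputs are
    extended to the grid edges with nearest-value extrapolation, 10-2 inputs
    contribute only inside their own extent (NaN elsewhere).
    """
    if len(grid_df) == 0:
        raise ValueError("empty perimetry grid")
    pts = grid_df[["azimuth_deg", "elevation_deg"]].to_numpy(dtype=float)
    vals = grid_df["sensitivity_db"].to_numpy(dtype=float)
    mesh_az, mesh_el = np.meshgrid(az, el)
    out = LinearNDInterpolator(pts, vals)(mesh_az, mesh_el)
    if extrapolate_nearest:
        missing = np.isnan(out)
        if missing.any():
            nn = NearestNDInterpolator(pts, vals)
            out[missing] = nn(mesh_az[missing], mesh_el[missing])
    return out


def composite_map(
    od_242: pd.DataFrame,
    od_102: pd.DataFrame,
    os_242: pd.DataFrame,
    os_102: pd.DataFrame,
    grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
) -> PerimetryGrid:
    """Composite binocular map: cellwise mean of the four interpolated tests.

    Inputs are DataFrames with columns ``azimuth_deg``, ``elevation_deg``,
    ``sensitivity_db`` carrying each test's native point locations.
    """
    az, el = _grid_centres(grid_step_deg)
    maps = [
        _interp_map(od_242, az, el, extrapolate_nearest=True),
        _interp_map(od_102, az, el, extrapolate_nearest=False),
        _interp_map(os_242, az, el, extrapolate_nearest=True),
        _interp_map(os_102, az, el, extrapolate_nearest=False),
    ]
    with np.errstate(invalid="ignore"):
        comp = np.nanmean(np.stack(maps), axis=0)
    return PerimetryGrid(azimuth_deg=az, elevation_deg=el, sensitivity=comp, provenance="composite")


def deficit_metrics(
    grid: PerimetryGrid,
    blind_criterion_db: float = DEFAULT_BLIND_CRITERION_DB,
) -> DeficitMetrics:
    """Area-weighted deficit sums per hemifield/vertical partition, plus sparing."""
    blind = grid.sensitivity < blind_criterion_db
    areas = grid.cell_areas_deg2()
    az = np.broadcast_to(grid.azimuth_deg[None, :], blind.shape)
    el = np.broadcast_to(grid.elevation_deg[:, None], blind.shape)

    def _sum(mask):
        return float(np.sum(areas[mask & blind]))

    total = _sum(np.ones_like(blind, dtype=bool))
    left = _sum(az < 0)
    right = _sum(az > 0)
    upper = _sum(el > 0)
    lower = _sum(el < 0)

    disk10 = np.hypot(az, el) <= 10.0
    intact = ~blind
    sparing10 = float(np.sum(areas[disk10 & intact]) / np.sum(areas[disk10]))
    central24 = (np.abs(az) <= 24.0) & (np.abs(el) <= 24.0)
    sparing24 = float(np.sum(areas[central24 & intact]) / np.sum(areas[central24]))

    return DeficitMetrics(
        total_deficit_deg2=total,
        left_deficit_deg2=left,
        right_deficit_deg2=right,
        upper_deficit_deg2=upper,
        lower_deficit_deg2=lower,
        sparing_central10=sparing10,
        sparing_central24=sparing24,
    )


def deficit_steering_correlation(deficit_deg2, delta_rho) -> tuple[float, float]:
    """Pearson correlation between a deficit-area measure and delta-rho.

    Returns (r, p). Requires at least 3 paired observations and non-zero
    variance in both variables.
    """
    x = np.asarray(deficit_deg2, dtype=float)
    y = np.asarray(delta_rho, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
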