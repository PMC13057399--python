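import numpy as np
import pandas as pd
import pytest

from steergaze.road_geometry import (
    TrialSchedule,
    build_schedule,
    chain_trials,
)
from steergaze import gaze_pipeline as gp
from steergaze.synthetic_data import simulate_drive, simulate_gaze


@pytest.fixture(scope="session")
def schedule144():
    return build_schedule(seed=7)


@pytest.fixture(scope="session")
def small_schedule(schedule144):
    """First 12 trials of a shuffled schedule (keeps per-test runtime low)."""
    return TrialSchedule(trials=schedule144.trials[:12], seed=schedule144.seed)


@pytest.fixture(scope="session")
def small_chain(small_schedule):
    return chain_trials(small_schedule)


@pytest.fixture(scope="session")
def drive(small_schedule, small_chain):
    trace, truth = simulate_drive(small_schedule, seed=11, chain=small_chain)
    return trace, truth


@pytest.fixture(scope="session")
def gaze(drive, small_chain):
    trace, _ = drive
    return simulate_gaze(trace, small_chain, seed=13)


@pytest.fixture(scope="session")
def gaze_speed(drive, gaze):
    """Filtered gaze speed series for the default synthetic participant."""
    trace, _ = drive
    left, right, head, truth = gaze
    merged = gp.merge_cyclopean(gp.gate_confidence(left), gp.gate_confidence(right))
    rot = gp.upsample_head_orientation(head, merged["t"].to_numpy())
    giw = gp.to_world(merged[["dir_x", "dir_y", "dir_z"]].to_numpy(), rot)
    az, el = gp.az_el(giw)
    vel = gp.velocity_series(az, el, merged["t"].to_numpy())
    series = pd.DataFrame({"t": merged["t"], "azimuth_deg": az, "elevation_deg": el})
    return series, vel, truth, trace


def brute_force_runs(speed, t, threshold, min_duration):
    """Independent oracle: naive scan for supra-threshold runs."""
    events = []
    i, n = 0, len(speed)
    while i < n:
        if not np.isnan(speed[i]) and speed[i] > threshold:
            j = i
            while (
                j + 1 < n
                and not np.isnan(speed[j + 1])
                and speed[j + 1] > threshold
            ):
                j += 1
            if t[j] - t[i] >= min_duration:
                events.append((t[i], t[j]))
            i = j + 1
        else:
            i += 1
    return events
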