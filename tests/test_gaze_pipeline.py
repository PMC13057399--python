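import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from steergaze import gaze_pipeline as gp
from conftest import brute_force_runs


def eye_frame(t, dirs, conf=1.0):
    dirs = np.atleast_2d(dirs)
    return pd.DataFrame(
        {
            "t": t,
            "eye": "left",
            "dir_x": dirs[:, 0],
            "dir_y": dirs[:, 1],
            "dir_z": dirs[:, 2],
            "confidence": conf,
        }
    )


class TestGateConfidence:
    def test_boundary_is_strictly_below(self):
        df = eye_frame([0.0], [[0, 1, 0]], conf=[0.75])
        out = gp.gate_confidence(df)
        assert not out[["dir_x", "dir_y", "dir_z"]].isna().any().any()

    def test_full_confidence_noop(self):
        df = eye_frame(np.arange(3) / 120, np.tile([0.0, 1.0, 0.0], (3, 1)), conf=1.0)
        out = gp.gate_confidence(df)
        pd.testing.assert_frame_equal(out, df, check_dtype=False)

    def test_elementwise_nulling(self):
        df = eye_frame(np.arange(3) / 120, np.tile([0, 1, 0], (3, 1)),
                       conf=[0.5, 0.8, 0.74])
        out = gp.gate_confidence(df)
        assert out["dir_x"].isna().tolist() == [True, False, True]

    def test_out_of_range_confidence_rejected(self):
        df = eye_frame([0.0], [[0, 1, 0]], conf=[1.5])
        with pytest.raises(ValueError):
            gp.gate_confidence(df)


class TestMerge:
    def test_identical_vectors_pass_through(self):
        t = np.arange(5) / 120
        l = eye_frame(t, np.tile([0, 1, 0], (5, 1)))
        r = eye_frame(t, np.tile([0, 1, 0], (5, 1)))
        m = gp.merge_cyclopean(l, r)
        assert np.allclose(m[["dir_x", "dir_y", "dir_z"]], [0, 1, 0])

    def test_single_eye_null_uses_other(self):
        t = np.array([0.0])
        l = eye_frame(t, [[np.nan, np.nan, np.nan]])
        r = eye_frame(t, [[0.0, 1.0, 0.0]])
        m = gp.merge_cyclopean(l, r)
        assert np.allclose(m[["dir_x", "dir_y", "dir_z"]].iloc[0], [0, 1, 0])

    def test_mean_is_renormalized(self):
        t = np.array([0.0])
        m = gp.merge_cyclopean(
            eye_frame(t, [[1.0, 0.0, 0.0]]), eye_frame(t, [[0.0, 1.0, 0.0]])
        )
        v = m[["dir_x", "dir_y", "dir_z"]].iloc[0].to_numpy()
        assert np.allclose(v, [1 / np.sqrt(2), 1 / np.sqrt(2), 0.0])

    def test_union_timestamps_and_both_null(self):
        l = eye_frame(np.array([0.0]), [[np.nan] * 3])
        r = eye_frame(np.array([1 / 240]), [[np.nan] * 3])
        m = gp.merge_cyclopean(l, r)
        assert len(m) == 2
        assert m[["dir_x", "dir_y", "dir_z"]].isna().all().all()

    def test_partner_beyond_half_frame_ignored(self):
        l = eye_frame(np.array([0.0]), [[1.0, 0.0, 0.0]])
        r = eye_frame(np.array([0.02]), [[0.0, 1.0, 0.0]])  # 20 ms away
        m = gp.merge_cyclopean(l, r)
        assert np.allclose(m[["dir_x", "dir_y", "dir_z"]].iloc[0], [1, 0, 0])


class TestToWorld:
    def test_identity(self):
        v = np.array([[0.0, 1.0, 0.0]])
        assert np.allclose(gp.to_world(v, Rotation.identity()), v)

    def test_quarter_turn_yaw(self):
        rot = Rotation.from_euler("z", 90, degrees=True)
        out = gp.to_world(np.array([[0.0, 1.0, 0.0]]), rot)
        assert np.allclose(out, [[-1.0, 0.0, 0.0]], atol=1e-12)

    def test_norm_preserved(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(50, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        rot = Rotation.random(50, rng=rng)
        out = gp.to_world(v, rot)
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            gp.to_world(np.array([[0, 1, 0.0]]), np.eye(3) * 2.0)


class TestAzEl:
    def test_reference_direction(self):
        az, el = gp.az_el(np.array([[0.0, 1.0, 0.0]]))
        assert az[0] == pytest.approx(0.0) and el[0] == pytest.approx(0.0)

    def test_ten_degrees_right(self):
        d = np.array([[np.sin(np.radians(10)), np.cos(np.radians(10)), 0.0]])
        az, el = gp.az_el(d)
        assert az[0] == pytest.approx(10.0)
        assert el[0] == pytest.approx(0.0, abs=1e-9)

    def test_forty_five_elevation(self):
        d = np.array([[0.0, np.cos(np.radians(45)), np.sin(np.radians(45))]])
        az, el = gp.az_el(d)
        assert az[0] == pytest.approx(0.0) and el[0] == pytest.approx(45.0)

    def test_straight_up_is_null(self):
        az, el = gp.az_el(np.array([[0.0, 0.0, 1.0]]))
        assert np.isnan(az[0])

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(min_value=-179.9, max_value=180.0),
        st.floats(min_value=-88.9, max_value=88.9),
    )
    def test_round_trip(self, az_deg, el_deg):
        a, e = np.radians(az_deg), np.radians(el_deg)
        d = np.array([[np.sin(a) * np.cos(e), np.cos(a) * np.cos(e), np.sin(e)]])
        az, el = gp.az_el(d)
        assert az[0] == pytest.approx(az_deg, abs=1e-9)
        assert el[0] == pytest.approx(el_deg, abs=1e-9)


class TestVelocity:
    def test_constant_position_zero_speed(self):
        t = np.arange(100) / 240
        vel = gp.velocity_series(np.full(100, 3.0), np.full(100, -7.0), t)
        assert np.allclose(vel["speed"], 0.0)

    def test_ramp_recovers_slope(self):
        t = np.arange(200) / 240
        vel = gp.velocity_series(10.0 * t, np.zeros(200), t)
        assert np.allclose(vel["speed"][5:-5], 10.0, atol=1e-6)

    def test_single_corrupt_sample_removed_by_median(self):
        t = np.arange(200) / 240
        az = np.zeros(200)
        az[100] = 5.0  # one-sample glitch
        vel = gp.velocity_series(az, np.zeros(200), t)
        # the mean filter spreads the impulse but the median filter kills it
        assert np.nanmax(vel["speed"]) < 15.0

    def test_too_few_valid_samples(self):
        t = np.arange(5) / 240
        vel = gp.velocity_series(np.zeros(5), np.zeros(5), t)
        assert vel.empty

    def test_nulls_propagate(self):
        t = np.arange(50) / 240
        az = np.zeros(50)
        az[20:23] = np.nan
        vel = gp.velocity_series(az, np.zeros(50), t)
        assert vel["speed"][20:23].isna().all()


class TestAdaptiveThreshold:
    def test_default_participant_near_25(self, gaze_speed):
        _, vel, _, _ = gaze_speed
        thr = gp.adaptive_threshold(vel["speed"].to_numpy())
        assert thr == pytest.approx(25.0, abs=5.0)

    def test_noise_tripled_capped_at_60(self, gaze_speed):
        _, vel, _, _ = gaze_speed
        thr = gp.adaptive_threshold(3.0 * vel["speed"].to_numpy())
        assert 15.0 <= thr <= 60.0
        assert thr > gp.adaptive_threshold(vel["speed"].to_numpy())

    def test_zero_noise_clamps_at_floor(self):
        assert gp.adaptive_threshold(np.zeros(100)) == 15.0

    def test_all_null_rejected(self):
        with pytest.raises(ValueError):
            gp.adaptive_threshold(np.full(10, np.nan))


class TestDetectSaccades:
    def test_flat_zero(self):
        t = np.arange(100) / 240
        assert gp.detect_saccades(np.zeros(100), t, 25.0) == []

    def test_two_long_pulses_one_short(self):
        t = np.arange(0, 1.0, 1 / 240)
        speed = np.zeros_like(t)
        speed[(t >= 0.1) & (t < 0.13)] = 30.0   # 30 ms
        speed[(t >= 0.5) & (t < 0.53)] = 30.0   # 30 ms
        speed[(t >= 0.8) & (t < 0.81)] = 30.0   # 10 ms
        events = gp.detect_saccades(speed, t, 25.0)
        assert len(events) == 2
        oracle = brute_force_runs(speed, t, 25.0, 0.025)
        assert len(oracle) == 2

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equivalence_with_brute_force_scanner(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        t = np.arange(n) / 240
        speed = np.abs(rng.normal(10, 15, n))
        speed[rng.random(n) < 0.05] = np.nan
        events = gp.detect_saccades(speed, t, 25.0)
        oracle = brute_force_runs(speed, t, 25.0, 0.025)
        assert [(e.onset_s, e.offset_s) for e in events] == oracle

    def test_gap_splits_runs(self):
        t = np.concatenate([np.arange(10) / 240, 0.5 + np.arange(10) / 240])
        speed = np.full_like(t, 30.0)
        events = gp.detect_saccades(speed, t, 25.0)
        assert len(events) == 2


class TestOutlierTrials:
    def test_all_equal_none_removed(self):
        assert gp.remove_outlier_trials([5] * 10).all()

    def test_extreme_count_removed(self):
        counts = [5, 6, 5, 4, 5, 6, 5, 4, 5, 6, 5, 4, 5, 6, 5, 4, 5, 6, 5, 50]
        keep = gp.remove_outlier_trials(counts)
        assert not keep[-1]
        assert keep[:-1].all()

    def test_idempotent(self):
        counts = np.array([5, 6, 5, 4, 5, 6, 5, 4, 5, 6, 5, 4, 5, 6, 5, 4, 5, 6, 5, 50])
        keep = gp.remove_outlier_trials(counts)
        again = gp.remove_outlier_trials(counts[keep])
        assert again.all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            gp.remove_outlier_trials([5, 5])


class TestTrialGazeSummary:
    def _series(self, az):
        t = np.arange(len(az)) / 240
        return pd.DataFrame(
            {"t": t, "azimuth_deg": az, "elevation_deg": np.full(len(az), -7.0)}
        )

    def test_left_turn_negated(self):
        s = self._series(np.full(240, -8.0))
        out = gp.trial_gaze_summary(s, (0.0, 1.0), "left")
        assert out.mean_azimuth_deg == pytest.approx(8.0)

    def test_mirror_symmetry(self):
        left = gp.trial_gaze_summary(self._series(np.full(240, -8.0)), (0, 1), "left")
        right = gp.trial_gaze_summary(self._series(np.full(240, 8.0)), (0, 1), "right")
        assert left.mean_azimuth_deg == pytest.approx(right.mean_azimuth_deg)

    def test_all_null_window_flagged(self):
        s = self._series(np.full(240, np.nan))
        out = gp.trial_gaze_summary(s, (0.0, 1.0), "left")
        assert not out.valid and np.isnan(out.mean_azimuth_deg)

    def test_saccade_count_in_window(self):
        s = self._series(np.zeros(240))
        events = [
            gp.SaccadeEvent(0.1, 0.14, 100.0),
            gp.SaccadeEvent(0.95, 0.99, 100.0),
        ]
        out = gp.trial_gaze_summary(s, (0.0, 0.5), "right", events)
        assert out.saccade_count == 1


class TestEndToEnd:
    def test_null_motion_input_gives_null_result(self):
        # Gaze = body forward, identity head rotation, full confidence.
        t_l = np.arange(0, 2, 1 / 120)
        t_r = t_l + 1 / 240
        fwd = np.tile([0.0, 1.0, 0.0], (len(t_l), 1))
        l = eye_frame(t_l, fwd)
        r = eye_frame(t_r, fwd)
        m = gp.merge_cyclopean(gp.gate_confidence(l), gp.gate_confidence(r))
        giw = gp.to_world(m[["dir_x", "dir_y", "dir_z"]].to_numpy(), Rotation.identity())
        az, el = gp.az_el(giw)
        assert np.allclose(az, 0.0) and np.allclose(el, 0.0)
        vel = gp.velocity_series(az, el, m["t"].to_numpy())
        assert gp.detect_saccades(vel["speed"].to_numpy(), vel["t"].to_numpy(), 15.0) == []

    def test_valid_counts_monotone_through_chain(self, gaze):
        left, right, head, _ = gaze
        gated_l = gp.gate_confidence(left)
        gated_r = gp.gate_confidence(right)
        n_valid_gate = (~gated_l["dir_x"].isna()).sum() + (~gated_r["dir_x"].isna()).sum()
        assert n_valid_gate <= len(left) + len(right)
        merged = gp.merge_cyclopean(gated_l, gated_r)
        rot = gp.upsample_head_orientation(head, merged["t"].to_numpy())
        giw = gp.to_world(merged[["dir_x", "dir_y", "dir_z"]].to_numpy(), rot)
        n_valid_world = (~np.isnan(giw).any(axis=1)).sum()
        n_valid_merge = (~merged["dir_x"].isna()).sum()
        assert n_valid_world <= n_valid_merge <= len(merged)
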