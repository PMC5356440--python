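import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from mtcortex import (CometTrack, DegenerateInputError, InvalidParameterError,
                      dynamics_summary, link_detections, segment_events,
                      speed_groups, split_on_bend)
from mtcortex import synthetic as sy
from mtcortex.geometry import orientation_difference


def make_track(positions, frame_interval=1.0, **kw):
    positions = np.asarray(positions, float)
    return CometTrack("t0", np.arange(len(positions)), positions,
                      frame_interval, **kw)


def track_from_angles(seg_angles_deg, step=1.0):
    """Build a track whose consecutive segment orientations are as given."""
    pos = [np.zeros(2)]
    for a in np.radians(seg_angles_deg):
        pos.append(pos[-1] + step * np.array([np.cos(a), np.sin(a)]))
    return make_track(pos)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

class TestLinking:
    def test_single_moving_detection_gives_one_track(self):
        frames = [[(0.1 * t, 0.0)] for t in range(10)]
        tracks = link_detections(frames, max_disp=0.5)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 10

    def test_gap_contract(self):
        # detection missing for max_gap+1 frames -> track terminated
        frames = [[(0.0, 0.0)], [(0.1, 0.0)], [], [], [(0.3, 0.0)], [(0.4, 0.0)]]
        tracks = link_detections(frames, max_disp=0.5, max_gap=1)
        assert len(tracks) == 2
        # with a big enough gap budget the track survives
        tracks = link_detections(frames, max_disp=0.5, max_gap=2)
        assert len(tracks) == 1

    def test_crossing_tracks_match_optimal_assignment(self):
        """Two constant-velocity comets crossing: greedy = optimal matching."""
        ts = np.arange(8, dtype=float)
        a = np.column_stack([ts, 0.5 * ts])          # heads north-east
        b = np.column_stack([ts, 7.0 - 0.5 * ts])    # heads south-east
        frames = [[tuple(a[t]), tuple(b[t])] for t in range(8)]
        tracks = link_detections(frames, max_disp=1.3)
        assert len(tracks) == 2
        # oracle: per-frame optimal assignment via the Hungarian algorithm
        got = {tuple(map(tuple, np.round(t.positions, 6))) for t in tracks}
        prev = {0: [a[0]], 1: [b[0]]}
        for t in range(1, 8):
            dets = np.array([a[t], b[t]])
            last = np.array([prev[0][-1], prev[1][-1]])
            cost = np.hypot(last[:, None, 0] - dets[None, :, 0],
                            last[:, None, 1] - dets[None, :, 1])
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                prev[r].append(dets[c])
        expected = {tuple(map(tuple, np.round(np.array(v), 6)))
                    for v in prev.values()}
        assert got == expected

    def test_no_detections(self):
        assert link_detections([[], [], []], max_disp=1.0) == []


# ---------------------------------------------------------------------------
# bend splitting
# ---------------------------------------------------------------------------

class TestSplitOnBend:
    def test_collinear_track_unchanged(self):
        track = make_track([[0, 0], [1, 0], [2, 0], [3, 0]])
        assert split_on_bend(track) == [track]

    def test_threshold_is_strict(self):
        # 25 <= 30: no split; 40 > 30: split into two fragments
        assert len(split_on_bend(track_from_angles([0, 25]))) == 1
        frags = split_on_bend(track_from_angles([0, 40]))
        assert len(frags) == 2
        assert [f.n_frames for f in frags] == [2, 2]
        assert frags[0].track_id.startswith("t0#")

    def test_exactly_30_degrees_does_not_split(self):
        assert len(split_on_bend(track_from_angles([0, 30]))) == 1

    def test_brute_force_oracle_on_random_walks(self):
        """Fragmentation matches an independent scan over segment pairs."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = rng.integers(3, 12)
            steps = rng.normal(0, 0.3, size=(n, 2))
            steps[np.hypot(steps[:, 0], steps[:, 1]) < 1e-6] += 0.1
            pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            track = make_track(pos)
            frags = split_on_bend(track, theta_max=30.0)
            # oracle: directly scan consecutive segment-angle differences
            ang = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))
            cuts = [i for i in range(len(ang) - 1)
                    if orientation_difference(ang[i], ang[i + 1]) > 30.0]
            assert len(frags) == len(cuts) + 1
            # frame partition must be exact
            sizes = [f.n_frames for f in frags]
            bounds = [-1] + cuts + [len(ang) - 1]
            expected_sizes = [bounds[k + 1] - bounds[k] + 1
                              for k in range(len(bounds) - 1)]
            assert sizes == expected_sizes

    def test_splitting_preserves_frames(self):
        track = track_from_angles([0, 50, 50, -40, 0])
        frags = split_on_bend(track)
        total = sum(f.n_frames for f in frags)
        # each split duplicates the boundary frame into both fragments
        assert total == track.n_frames + (len(frags) - 1)
        for f in frags:
            assert f.frame_interval == track.frame_interval


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

class TestSegmentEvents:
    def test_constant_growth(self):
        # 10 µm/min at 1 s/frame = 1/6 µm per frame
        pos = [[i / 6.0, 0.0] for i in range(10)]
        events = segment_events(make_track(pos), pause_speed_max=1.5)
        assert len(events) == 1
        assert events[0].state == "growth"
        assert events[0].mean_speed == pytest.approx(10.0)

    def test_hand_enumerated_run_lengths(self):
        # frame speeds [12, 12, 0.5, 0.5, 12] -> growth, pause, growth
        per_min = 1.0 / 60.0
        speeds = [12, 12, 0.5, 0.5, 12]
        xs = np.concatenate([[0.0], np.cumsum([s * per_min for s in speeds])])
        events = segment_events(make_track([[x, 0] for x in xs]),
                                pause_speed_max=1.5, min_pause_frames=2)
        assert [e.state for e in events] == ["growth", "pause", "growth"]
        assert events[1].mean_speed == pytest.approx(0.5)

    def test_all_below_threshold_single_pause(self):
        pos = [[0.001 * i, 0] for i in range(6)]
        events = segment_events(make_track(pos), pause_speed_max=1.5)
        assert [e.state for e in events] == ["pause"]

    def test_short_track_classified_by_mean_speed(self):
        events = segment_events(make_track([[0, 0], [1, 0]]),
                                pause_speed_max=1.5, min_pause_frames=2)
        assert len(events) == 1
        assert events[0].state == "growth"

    def test_isolated_subthreshold_frame_stays_growth(self):
        per_min = 1.0 / 60.0
        speeds = [12, 0.5, 12]
        xs = np.concatenate([[0.0], np.cumsum([s * per_min for s in speeds])])
        events = segment_events(make_track([[x, 0] for x in xs]),
                                pause_speed_max=1.5, min_pause_frames=2)
        assert [e.state for e in events] == ["growth"]

    def test_events_tile_track(self):
        """Events are contiguous, non-overlapping, and cover all frames."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(3, 30)
            steps = rng.choice([0.005, 0.2], size=n) * rng.standard_normal((n,))
            pos = np.column_stack([np.concatenate([[0], np.cumsum(steps)]),
                                   np.zeros(n + 1)])
            track = make_track(pos)
            events = segment_events(track)
            assert events[0].start_frame == track.frames[0]
            assert events[-1].end_frame == track.frames[-1]
            for a, b in zip(events, events[1:]):
                assert a.end_frame == b.start_frame
            assert sum(e.n_segments for e in events) == track.n_frames - 1

    def test_brute_force_event_oracle(self):
        """Event boundaries equal an independent run-length enumeration."""
        rng = np.random.default_rng(17)
        thresh, min_run = 1.5, 2
        for _ in range(1000):
            n = rng.integers(2, 25)
            speeds = rng.choice([0.3, 0.8, 5.0, 12.0], size=n)
            xs = np.concatenate([[0.0], np.cumsum(speeds / 60.0)])
            track = make_track([[x, 0] for x in xs])
            events = segment_events(track, thresh, min_run)
            # oracle: mark sub-threshold runs of >= min_run, then group
            below = speeds < thresh
            pause = np.zeros(n, bool)
            i = 0
            while i < n:
                if below[i]:
                    j = i
                    while j + 1 < n and below[j + 1]:
                        j += 1
                    if j - i + 1 >= min_run:
                        pause[i:j + 1] = True
                    i = j + 1
                else:
                    i += 1
            if n < min_run:
                expected = ["pause" if speeds.mean() < thresh else "growth"]
            else:
                expected = [("pause" if pause[k] else "growth")
                            for k in range(n)
                            if k == 0 or pause[k] != pause[k - 1]]
            assert [e.state for e in events] == expected


# ---------------------------------------------------------------------------
# summaries and speed groups
# ---------------------------------------------------------------------------

class TestDynamicsSummary:
    def test_unit_arithmetic(self):
        # 2 px/frame at 0.1 µm/px and 1 s/frame -> 0.2 µm/s -> 12 µm/min
        pos = [[0.2 * i, 0.0] for i in range(5)]
        track = make_track(pos, frame_interval=1.0)
        events = segment_events(track)
        per_cell, per_treatment = dynamics_summary([track], [events])
        assert per_cell.mean_growth_speed_um_min[0] == pytest.approx(12.0)

    def test_single_growth_event_length(self):
        pos = [[0.2 * i, 0.0] for i in range(5)]
        events = segment_events(make_track(pos))
        assert events[0].path_length == pytest.approx(0.8)

    def test_parameter_recovery_from_simulator(self):
        """Pipeline recovers the generator's growth speed and pause share."""
        v_true, p_gp, p_pg = 12.0, 0.1, 0.3
        for seed in (1, 2, 3):
            tracks = sy.simulate_dynamic_tracks(500, v_true, 2.0, p_gp, p_pg,
                                                seed=seed)
            events = [segment_events(t) for t in tracks]
            _, per_treatment = dynamics_summary(tracks, events)
            v = per_treatment.mean_growth_speed_um_min[0]
            assert abs(v - v_true) / v_true < 0.05
            pause_time = 1.0 - per_treatment.pct_time_growing[0] / 100.0
            assert abs(pause_time - p_gp / (p_gp + p_pg)) < 0.1

    def test_no_tracks_degenerate(self):
        with pytest.raises(DegenerateInputError):
            dynamics_summary([], [])


class TestSpeedGroups:
    def test_vmax_rule_on_constructed_input(self):
        # fastest cell has mean 12, SD 3 -> vmax 15
        df = pd.DataFrame({
            "cell_id": ["a"] * 3 + ["b"] * 3,
            "treatment": ["control"] * 6,
            "speed": [10.0, 10.0, 10.0, 9.0, 12.0, 15.0],
        })
        tables = speed_groups(df)
        assert tables["control"].vmax == pytest.approx(15.0)

    def test_equal_quarter_bins(self):
        df = pd.DataFrame({
            "cell_id": ["c"] * 4 + ["f"] * 2,
            "treatment": ["control"] * 4 + ["control"] * 2,
            "speed": [1.0, 5.0, 9.0, 14.0, 16.0, 16.0],
        })
        # fastest cell 'f': mean 16, SD 0 -> vmax 16, bins of width 4
        tables = speed_groups(df)
        t = tables["control"]
        assert t.vmax == pytest.approx(16.0)
        np.testing.assert_allclose(t.edges, [0, 4, 8, 12, 16])
        # speeds 1,5,9,14 -> one per bin; the two 16s land in the top bin
        np.testing.assert_allclose(t.counts, [1, 1, 1, 3])
        assert t.percentages.sum() == pytest.approx(100.0)

    def test_speeds_above_vmax_in_top_bin(self):
        df = pd.DataFrame({"cell_id": ["a"] * 4, "treatment": ["x"] * 4,
                           "speed": [1.0, 2.0, 3.0, 50.0]})
        t = speed_groups(df)["x"]
        assert t.counts[-1] >= 1
        assert t.percentages.sum() == pytest.approx(100.0)

    def test_slowdown_increases_very_slow_share(self):
        """Shifting all speeds down inflates the very-slow bin."""
        rng = np.random.default_rng(8)
        fast = rng.normal(12, 2, 200).clip(0)
        slow = rng.normal(6, 2, 200).clip(0)
        df = pd.DataFrame({
            "cell_id": ["c"] * 200 + ["t"] * 200,
            "treatment": ["control"] * 200 + ["inhibited"] * 200,
            "speed": np.concatenate([fast, slow]),
        })
        tables = speed_groups(df)
        assert tables["inhibited"].percentages[0] > tables["control"].percentages[0]

    def test_percentages_sum_to_100_per_treatment(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "cell_id": rng.choice(list("abcd"), 300),
            "treatment": rng.choice(["control", "treated"], 300),
            "speed": rng.gamma(4, 2, 300),
        })
        for t in speed_groups(df).values():
            assert t.percentages.sum() == pytest.approx(100.0)
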