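"""Detector behaviour: pose estimation, gesture detection against generator
truth, event matching vs a brute-force oracle, and window restriction."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from smoketop.puff_segmentation import (
    RestingPose,
    SegmentationParams,
    detect_puffs,
    estimate_resting_pose,
    match_events,
    restrict_to_window,
)
from smoketop.session_model import AccelTrace, PuffEvent, ValidationError
from smoketop.synthetic_session import SimulationConfig, simulate_session


def _flat_trace(n=2000, pose=(9.0, -1.0, 5.0), rate=30.0):
    t = np.floor(np.arange(n) * 1000 / rate + 0.5)
    return AccelTrace(
        t_ms=t,
        x=np.full(n, pose[0]),
        y=np.full(n, pose[1]),
        z=np.full(n, pose[2]),
        sampling_rate=rate,
    )


class TestRestingPose:
    def test_constant_trace_recovers_pose_exactly(self, seg_params):
        pose = estimate_resting_pose(_flat_trace(), seg_params)
        assert (pose.x, pose.y, pose.z) == (9.0, -1.0, 5.0)
        assert pose.dispersion == (0.0, 0.0, 0.0)

    def test_simulated_session_pose_within_tolerance(self, seg_params):
        cfg = SimulationConfig(seed=5, noise_sd=0.2)
        trace, _, _ = simulate_session(cfg)
        pose = estimate_resting_pose(trace, seg_params)
        assert abs(pose.x - cfg.rest_pose[0]) < 0.1
        assert abs(pose.y - cfg.rest_pose[1]) < 0.1
        assert abs(pose.z - cfg.rest_pose[2]) < 0.1

    def test_short_trace_rejected(self, seg_params):
        with pytest.raises(ValidationError):
            estimate_resting_pose(_flat_trace(n=100), seg_params)

    def test_all_plateau_trace_locks_onto_plateau(self, seg_params):
        # documented hazard: a trace that is one long plateau yields the plateau
        pose = estimate_resting_pose(_flat_trace(pose=(9.0, -5.0, -3.0)), seg_params)
        assert (pose.y, pose.z) == (-5.0, -3.0)


class TestDetectPuffs:
    def test_flat_trace_yields_nothing(self, seg_params):
        trace = _flat_trace()
        pose = RestingPose(9.0, -1.0, 5.0)
        assert detect_puffs(trace, pose, seg_params) == []

    def test_single_trapezoidal_puff_duration(self, seg_params):
        """A 60-sample plateau at 30 Hz reads out as a 2000 ms puff."""
        n, rate = 400, 30.0
        rest = np.array([9.0, -1.0, 5.0])
        plateau = np.array([9.0, -5.0, -3.0])
        sig = np.tile(rest[:, None], (1, n)).astype(float)
        sig[:, 100:160] = plateau[:, None]
        t = np.floor(np.arange(n) * 1000 / rate + 0.5)
        trace = AccelTrace(t_ms=t, x=sig[0], y=sig[1], z=sig[2], sampling_rate=rate)
        events = detect_puffs(trace, RestingPose(*rest), seg_params)
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(2000, abs=34)

    def test_zero_noise_session_matches_truth_within_2_samples(self, seg_params):
        cfg = SimulationConfig(seed=7, noise_sd=0.0)
        trace, truth, sched = simulate_session(cfg)
        pose = estimate_resting_pose(trace, seg_params)
        detected = detect_puffs(trace, pose, seg_params)
        watch_truth = [e for e in truth if e.hand == cfg.watch_hand]
        m = match_events(detected, watch_truth, max_offset_ms=1000)
        assert (m.true_positives, m.false_positives, m.misses) == (len(watch_truth), 0, 0)
        for di, ti in m.pairs:
            assert abs(detected[di].start_ms - watch_truth[ti].start_ms) <= 67
            assert abs(detected[di].end_ms - watch_truth[ti].end_ms) <= 67

    def test_confounders_do_not_trigger_detection(self, seg_params):
        cfg = SimulationConfig(seed=3, n_puffs_per_hand=0, noise_sd=0.2)
        trace, _, _ = simulate_session(cfg)
        pose = estimate_resting_pose(trace, seg_params)
        assert detect_puffs(trace, pose, seg_params) == []

    def test_events_sorted_nonoverlapping_min_length(self, seg_params):
        cfg = SimulationConfig(seed=13, noise_sd=0.5)
        trace, _, _ = simulate_session(cfg)
        pose = estimate_resting_pose(trace, seg_params)
        events = detect_puffs(trace, pose, seg_params)
        assert events, "expected detections on a default session"
        for a, b in zip(events, events[1:]):
            assert a.end_ms <= b.start_ms
        assert all(e.duration_ms >= seg_params.min_plateau_ms for e in events)

    def test_raising_min_plateau_never_adds_events(self, seg_params):
        cfg = SimulationConfig(seed=21, noise_sd=0.5)
        trace, _, _ = simulate_session(cfg)
        pose = estimate_resting_pose(trace, seg_params)
        counts = []
        for min_plateau in (300.0, 500.0, 900.0, 1300.0, 2500.0):
            p = seg_params.model_copy(update={"min_plateau_ms": min_plateau})
            counts.append(len(detect_puffs(trace, pose, p)))
        assert counts == sorted(counts, reverse=True)


def _brute_force_max_matching(detected, truth, max_offset_ms):
    """Oracle: maximum-cardinality bipartite matching under the offset cap."""
    if not detected or not truth:
        return 0
    adj = np.zeros((len(detected), len(truth)), dtype=bool)
    for i, d in enumerate(detected):
        for j, t in enumerate(truth):
            adj[i, j] = abs(d.mid_ms - t.mid_ms) <= max_offset_ms
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int((match >= 0).sum())


class TestMatchEvents:
    def test_identical_lists_all_match(self):
        evs = [PuffEvent(i * 1000, i * 1000 + 500) for i in range(5)]
        m = match_events(evs, evs, 1000)
        assert (m.true_positives, m.false_positives, m.misses) == (5, 0, 0)
        assert m.precision == m.recall == 1.0

    def test_empty_detected_all_missed(self):
        truth = [PuffEvent(i * 1000, i * 1000 + 500) for i in range(5)]
        m = match_events([], truth, 1000)
        assert (m.true_positives, m.false_positives, m.misses) == (0, 0, 5)

    def test_counts_partition_both_lists(self, seg_params):
        cfg = SimulationConfig(seed=17, noise_sd=0.5)
        trace, truth, _ = simulate_session(cfg)
        pose = estimate_resting_pose(trace, seg_params)
        detected = detect_puffs(trace, pose, seg_params)
        watch_truth = [e for e in truth if e.hand == "left"]
        m = match_events(detected, watch_truth, 1000)
        assert m.true_positives + m.false_positives == len(detected)
        assert m.true_positives + m.misses == len(watch_truth)

    def test_matches_brute_force_optimum_on_seeded_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            truth, detected, t = [], [], 0
            for _ in range(rng.integers(2, 8)):
                t += int(rng.integers(2000, 9000))
                d = int(rng.integers(800, 2500))
                truth.append(PuffEvent(t, t + d))
                if rng.random() < 0.8:  # jittered detection
                    off = int(rng.integers(-400, 400))
                    detected.append(PuffEvent(t + off, t + d + off))
                t += d
            m = match_events(detected, truth, max_offset_ms=1000)
            assert m.true_positives == _brute_force_max_matching(
                detected, truth, 1000
            )


class TestRestrictToWindow:
    def test_inside_events_kept(self):
        evs = [PuffEvent(1000, 2000), PuffEvent(3000, 4000)]
        assert restrict_to_window(evs, 0, 10000) == evs

    def test_straddling_event_dropped_not_truncated(self):
        evs = [PuffEvent(1000, 2000), PuffEvent(9000, 11000)]
        assert restrict_to_window(evs, 0, 10000) == [PuffEvent(1000, 2000)]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValidationError):
            restrict_to_window([], 100, 100)

    def test_watch_segment_restriction_recovers_hand_truth(self, short_config):
        _, truth, sched = simulate_session(short_config)
        a, b = sched.smoking_window_ms("left")
        left = [e for e in truth if e.hand == "left"]
        assert restrict_to_window(truth, a, b) == left
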