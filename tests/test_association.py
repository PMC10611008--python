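"""Score partitioning and two-stage class-gated association."""

import itertools

import numpy as np
import pytest

from fruittrack import (BoundingBox, Detection, Tracker, TrackerConfig,
                        byte_associate, iou, match, partition_by_score)
from fruittrack.association import ConfigError
from tests.helpers import make_det, moving_target_stream


def scores_of(dets):
    return [d.score for d in dets]


class TestPartition:
    def test_three_way_split(self):
        dets = [make_det(score=s) for s in (0.9, 0.3, 0.05)]
        high, low, discarded = partition_by_score(dets, 0.6, 0.1)
        assert scores_of(high) == [0.9]
        assert scores_of(low) == [0.3]
        assert scores_of(discarded) == [0.05]

    def test_empty_input(self):
        assert partition_by_score([], 0.6, 0.1) == ([], [], [])

    def test_boundaries_use_closed_lower_edges(self):
        dets = [make_det(score=s) for s in (0.6, 0.1)]
        high, low, discarded = partition_by_score(dets, 0.6, 0.1)
        assert scores_of(high) == [0.6]      # score == tau_high -> high
        assert scores_of(low) == [0.1]       # score == tau_low -> low
        assert discarded == []

    def test_partition_exhaustive_order_preserving(self, rng):
        dets = [make_det(score=s) for s in rng.uniform(0, 1, size=40)]
        high, low, discarded = partition_by_score(dets, 0.55, 0.2)
        assert sorted(map(id, high + low + discarded)) == sorted(map(id, dets))
        for part in (high, low, discarded):
            indices = [dets.index(d) for d in part]
            assert indices == sorted(indices)

    def test_bad_threshold_order_rejected(self):
        with pytest.raises(ConfigError):
            partition_by_score([], 0.1, 0.6)


def _tracks_from(dets, config=None):
    """Instantiate tracks directly from detections (fresh tracker)."""
    tracker = Tracker(config or TrackerConfig())
    tracker.step(dets)
    return tracker, tracker.tracks


class TestMatch:
    def test_single_overlapping_pair_matches(self):
        _, tracks = _tracks_from([make_det(frame=0)])
        det = make_det(frame=1, x=103.0)
        result = match(tracks, [det], min_iou=0.2)
        assert result.matches == [(tracks[0].track_id, 0)]
        assert result.unmatched_tracks == [] and result.unmatched_detections == []

    def test_class_gate_blocks_cross_class_pair(self):
        _, tracks = _tracks_from([make_det(cls="flower")])
        det = make_det(frame=1, cls="red_fruit")
        result = match(tracks, [det], min_iou=0.2, class_gated=True)
        assert result.matches == []
        assert result.unmatched_tracks == [tracks[0].track_id]
        assert result.unmatched_detections == [0]

    def test_gate_off_allows_cross_class(self):
        _, tracks = _tracks_from([make_det(cls="flower")])
        result = match(tracks, [make_det(frame=1, cls="red_fruit")],
                       min_iou=0.2, class_gated=False)
        assert len(result.matches) == 1

    def test_low_iou_assignment_demoted(self):
        _, tracks = _tracks_from([make_det(x=0.0, y=0.0)])
        far = make_det(frame=1, x=500.0, y=500.0)
        result = match(tracks, [far], min_iou=0.2)
        assert result.matches == []

    def test_result_partitions_inputs(self, rng):
        dets0 = [make_det(x=200.0 * i, cls="flower") for i in range(4)]
        _, tracks = _tracks_from(dets0)
        dets1 = [make_det(frame=1, x=200.0 * i + rng.uniform(-30, 30))
                 for i in range(6)]
        result = match(tracks, dets1, min_iou=0.1)
        seen_tracks = [t for t, _ in result.matches] + result.unmatched_tracks
        seen_dets = [j for _, j in result.matches] + result.unmatched_detections
        assert sorted(seen_tracks) == sorted(t.track_id for t in tracks)
        assert sorted(seen_dets) == list(range(len(dets1)))
        assert len(set(seen_dets)) == len(seen_dets)

    def test_assignment_matches_brute_force_optimum(self, rng):
        """Total matched IoU equals the max over all permutations."""
        for trial in range(30):
            n_t = int(rng.integers(1, 6))
            n_d = int(rng.integers(1, 6))
            dets0 = [make_det(x=float(rng.uniform(0, 500)),
                              y=float(rng.uniform(0, 500)),
                              w=float(rng.uniform(20, 80)),
                              h=float(rng.uniform(20, 80)))
                     for _ in range(n_t)]
            _, tracks = _tracks_from(dets0)
            dets1 = [make_det(frame=1, x=float(rng.uniform(0, 500)),
                              y=float(rng.uniform(0, 500)),
                              w=float(rng.uniform(20, 80)),
                              h=float(rng.uniform(20, 80)))
                     for _ in range(n_d)]
            result = match(tracks, dets1, min_iou=0.0)
            got = sum(iou(next(t for t in tracks if t.track_id == tid).predicted_box(),
                          dets1[j].box)
                      for tid, j in result.matches)
            boxes_t = [t.predicted_box() for t in tracks]
            best = 0.0
            k = min(n_t, n_d)
            for t_sub in itertools.permutations(range(n_t), k):
                for d_sub in itertools.combinations(range(n_d), k):
                    best = max(best, sum(iou(boxes_t[a], dets1[b].box)
                                         for a, b in zip(t_sub, d_sub)))
            assert got == pytest.approx(best, abs=1e-9)


class TestByteAssociate:
    def test_cold_start_promotes_high_detections(self):
        cfg = TrackerConfig()
        s1, s2, candidates = byte_associate(
            [], [make_det(score=0.9), make_det(x=400.0, score=0.8)], cfg)
        assert s1.matches == [] and s2.matches == []
        assert len(candidates) == 2

    def test_low_score_without_track_is_discarded(self):
        cfg = TrackerConfig()
        s1, s2, candidates = byte_associate([], [make_det(score=0.3)], cfg)
        assert s1.matches == [] and s2.matches == [] and candidates == []

    def test_occlusion_dip_recovered_in_stage_two(self):
        """A track whose score drops into the low band keeps matching."""
        cfg = TrackerConfig()
        tracker = Tracker(cfg)
        stream = moving_target_stream(
            10, score_fn=lambda k: 0.3 if 4 <= k < 7 else 0.9)
        ids_seen = set()
        for frame_dets in stream:
            for trk in tracker.step(frame_dets):
                ids_seen.add(trk.track_id)
        assert ids_seen == {1}

    def test_class_purity_over_random_streams(self, rng):
        cfg = TrackerConfig()
        tracker = Tracker(cfg)
        labels = ("flower", "green_fruit", "red_fruit")
        for k in range(30):
            dets = [make_det(frame=k, x=float(rng.uniform(0, 800)),
                             y=float(rng.uniform(0, 500)),
                             score=float(rng.uniform(0.05, 1.0)),
                             cls=labels[int(rng.integers(3))])
                    for _ in range(int(rng.integers(0, 8)))]
            s1, s2, _ = byte_associate(tracker.tracks, dets, cfg)
            for stage in (s1, s2):
                for tid, j in stage.matches:
                    trk = next(t for t in tracker.tracks if t.track_id == tid)
                    assert trk.class_label == stage.detections[j].class_label
            tracker.step(dets, frame_index=k)
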