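"""Counting accuracy (Pc/APc/mAPc) and detection accuracy (P/R/AP/mAP)."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fruittrack import (apc, average_precision, counting_accuracy,
                        evaluate_counts, evaluate_detections, mapc,
                        match_detections_to_truth, mean_ap, round_half_up)
from fruittrack.metrics import EvaluationError
from tests.helpers import make_det

# automated / true counts of the four inspection test videos
TABLE_COUNTS = {
    "flower": [(64, 66), (95, 95), (13, 13), (15, 16)],
    "green_fruit": [(43, 53), (51, 52), (49, 50), (79, 80)],
    "red_fruit": [(18, 18), (15, 18), (70, 77), (103, 110)],
}


class TestCountingAccuracy:
    @pytest.mark.parametrize("na, nt, expected", [
        (43, 53, 81.13),
        (79, 80, 98.75),
        (70, 77, 90.91),
        (103, 110, 93.64),
        (18, 18, 100.0),
        (15, 18, 83.33),
    ])
    def test_reported_video_accuracies(self, na, nt, expected):
        assert counting_accuracy(na, nt) == expected

    @given(st.integers(0, 500), st.integers(1, 500))
    def test_equals_100_iff_exact(self, na, nt):
        pc = counting_accuracy(na, nt)
        assert pc <= 100.0
        assert (pc == 100.0) == (na == nt)

    @given(st.integers(1, 300), st.integers(0, 100))
    def test_over_and_under_count_penalized_symmetrically(self, nt, d):
        d = min(d, nt)
        assert counting_accuracy(nt + d, nt) == counting_accuracy(nt - d, nt)

    def test_zero_truth_rejected(self):
        with pytest.raises(EvaluationError):
            counting_accuracy(5, 0)


class TestCountingAverages:
    def test_flower_apc_from_video_counts(self):
        pcs = [counting_accuracy(na, nt) for na, nt in TABLE_COUNTS["flower"]]
        assert apc(pcs) == 97.68

    def test_mapc_from_class_averages(self):
        assert mapc([97.68, 93.97, 91.89]) == 94.51

    @given(st.floats(0, 100), st.integers(1, 8))
    def test_apc_of_identical_values_is_identity(self, v, n):
        assert apc([round_half_up(v)] * n) == round_half_up(v)

    def test_order_invariance(self):
        vals = [97.68, 93.97, 91.89]
        for perm in itertools.permutations(vals):
            assert mapc(list(perm)) == 94.51

    def test_empty_inputs_rejected(self):
        with pytest.raises(EvaluationError):
            apc([])
        with pytest.raises(EvaluationError):
            mapc([])

    def test_evaluate_counts_table(self):
        truth = {(f"v{i+1}", cls): nt
                 for cls, pairs in TABLE_COUNTS.items()
                 for i, (_, nt) in enumerate(pairs)}
        pred = {(f"v{i+1}", cls): na
                for cls, pairs in TABLE_COUNTS.items()
                for i, (na, _) in enumerate(pairs)}
        result = evaluate_counts(pred, truth)
        assert result.apc_per_class["flower"] == 97.68
        row = result.per_video.query("video_id == 'v1' and class_label == 'green_fruit'")
        assert row["pc"].iloc[0] == 81.13
        # mAPc is the mean of the three per-class APc values
        assert result.mapc == mapc(list(result.apc_per_class.values()))

    def test_perfect_prediction_gives_all_100(self):
        truth = {("v1", "flower"): 10, ("v1", "red_fruit"): 7}
        result = evaluate_counts(dict(truth), truth)
        assert set(result.per_video["pc"]) == {100.0}
        assert result.mapc == 100.0


class TestDetectionMatching:
    def test_exact_overlap_is_tp(self):
        det, truth = make_det(score=0.9), make_det(score=1.0)
        matched = match_detections_to_truth([det], [truth])
        assert matched["tp"].tolist() == [True]

    def test_duplicate_detections_one_tp_one_fp(self):
        truth = make_det()
        dets = [make_det(score=0.9), make_det(score=0.8, x=102.0)]
        matched = match_detections_to_truth(dets, [truth])
        assert sorted(matched["tp"].tolist()) == [False, True]
        # the higher-scoring detection claims the truth
        assert matched.loc[matched["score"] == 0.9, "tp"].iloc[0]

    def test_cross_class_never_matches(self):
        matched = match_detections_to_truth(
            [make_det(cls="flower")], [make_det(cls="red_fruit")])
        assert matched["tp"].tolist() == [False]

    def test_greedy_matching_agrees_with_exhaustive_oracle(self, rng):
        """TP count from greedy score-descending matching equals the best
        achievable under a one-to-one IoU >= 0.5 constraint for these
        staircase layouts (greedy is optimal when IoU is all-or-nothing
        decisive per pair)."""
        for _ in range(20):
            truths = [make_det(x=float(120 * i), score=1.0) for i in range(3)]
            dets = [make_det(x=float(120 * i + rng.uniform(-80, 80)),
                             score=float(rng.uniform(0.1, 1.0)))
                    for i in range(4)]
            matched = match_detections_to_truth(dets, truths)
            got_tp = int(matched["tp"].sum())
            from fruittrack import iou
            best = 0
            for d_perm in itertools.permutations(range(len(dets)), len(truths)):
                tp = sum(iou(dets[d].box, truths[t].box) >= 0.5
                         for t, d in enumerate(d_perm))
                best = max(best, tp)
            assert got_tp == best


class TestAveragePrecision:
    def test_perfect_detector(self):
        scores = [0.9, 0.8, 0.7]
        assert average_precision(scores, [True] * 3, n_truth=3) == pytest.approx(1.0)

    def test_all_false_positives(self):
        assert average_precision([0.9, 0.8], [False, False], n_truth=3) == 0.0

    def test_no_detections(self):
        assert average_precision([], [], n_truth=2) == 0.0

    def test_undefined_without_truth(self):
        with pytest.raises(EvaluationError):
            average_precision([0.9], [True], n_truth=0)

    def test_matches_brute_force_envelope(self, rng):
        """All-point AP equals direct evaluation of the rectangle sum under
        the monotone precision envelope."""
        for _ in range(30):
            n = int(rng.integers(1, 20))
            flags = rng.uniform(size=n) < 0.5
            scores = rng.uniform(0.01, 1.0, size=n)
            n_truth = int(flags.sum()) + int(rng.integers(1, 5))
            got = average_precision(scores.tolist(), flags.tolist(), n_truth)
            order = np.argsort(-scores, kind="stable")
            tp = flags[order].astype(float)
            rec = np.cumsum(tp) / n_truth
            prec = np.cumsum(tp) / np.arange(1, n + 1)
            expected, prev_r = 0.0, 0.0
            for r in sorted(set(rec)):
                if r <= prev_r:
                    continue
                env = prec[rec >= r - 1e-12].max()
                expected += (r - prev_r) * env
                prev_r = r
            assert got == pytest.approx(expected, abs=1e-10)

    def test_eleven_point_variant_on_perfect_detector(self):
        assert average_precision([0.9, 0.8], [True, True], n_truth=2,
                                 interpolation="11_point") == pytest.approx(1.0)


class TestDetectionEval:
    def test_reported_class_aps_average_to_map(self):
        assert mean_ap([94.1, 94.8, 96.1]) == pytest.approx(95.0)

    def test_pred_equals_truth_gives_map_one(self):
        truths = [make_det(frame=f, x=100.0 * i, score=1.0,
                           cls=("flower", "green_fruit", "red_fruit")[i % 3])
                  for f in range(3) for i in range(3)]
        result = evaluate_detections(truths, truths)
        assert result.mean_ap == pytest.approx(1.0)
        assert (result.per_class["fp"] == 0).all()
        assert (result.per_class["fn"] == 0).all()

    def test_class_without_truth_excluded_with_warning(self):
        dets = [make_det(cls="flower", score=0.9),
                make_det(cls="red_fruit", score=0.8, x=300.0)]
        truths = [make_det(cls="flower", score=1.0)]
        with pytest.warns(UserWarning):
            result = evaluate_detections(dets, truths)
        assert result.skipped_classes == ["red_fruit"]
        assert result.mean_ap == pytest.approx(1.0)

    def test_map_invariant_to_class_ordering(self):
        assert mean_ap([96.1, 94.1, 94.8]) == pytest.approx(95.0)
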