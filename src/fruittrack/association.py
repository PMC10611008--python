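"""BYTE two-stage, class-gated data association.

Detections are split by confidence into a high band, a low band, and a
discarded remainder.  Stage 1 matches the high band against all live
(tracked + lost) tracks by IoU through a linear assignment; stage 2 gives
the tracks left unmatched — those that were actively tracked, with a fresh
box — a second chance against the low band, which is what recovers
occluded targets whose score dipped.  Unmatched high-score detections
become new-track candidates; unmatched low-score detections are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Detection, iou

if TYPE_CHECKING:  # pragma: no cover
    from .tracker import Track, TrackerConfig

#: sentinel cost for class-gated (forbidden) pairs; any IoU-derived cost is <= 1
_GATED_COST = 1e6


class ConfigError(ValueError):
    pass


@dataclass
class AssociationResult:
    """Outcome of one assignment round.

    Every input track and detection appears in exactly one of the three
    lists; ``matches`` pairs a track id with an index into the detection
    list that was passed in.
    """

    matches: list[tuple[int, int]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)
    #: the detection list the indices refer to (set by byte_associate)
    detections: list[Detection] = field(default_factory=list, repr=False)


def partition_by_score(
    dets: Sequence[Detection], tau_high: float, tau_low: float
) -> tuple[list[Detection], list[Detection], list[Detection]]:
    """Split detections into (high, low, discarded) confidence bands.

    high: score >= tau_high; low: tau_low <= score < tau_high;
    discarded: score < tau_low.  Input order is preserved in each part.
    """
    if not (0.0 <= tau_low < tau_high <= 1.0):
        raise ConfigError(
            f"score thresholds must satisfy 0 <= tau_low < tau_high <= 1, "
            f"got tau_low={tau_low}, tau_high={tau_high}"
        )
    high = [d for d in dets if d.score >= tau_high]
    low = [d for d in dets if tau_low <= d.score < tau_high]
    discarded = [d for d in dets if d.score < tau_low]
    return high, low, discarded


def match(
    tracks: Sequence["Track"],
    dets: Sequence[Detection],
    min_iou: float,
    class_gated: bool = True,
) -> AssociationResult:
    """Optimal one-to-one IoU matching between predicted tracks and detections.

    Solves the rectangular assignment problem on cost 1 - IoU(predicted
    box, detection box).  Cross-class pairs get a prohibitive cost when
    ``class_gated``; assignments below ``min_iou`` are demoted to
    unmatched.  Ties are broken deterministically: tracks are processed in
    (age descending, track_id ascending) order.
    """
    if not tracks or not dets:
        return AssociationResult(
            matches=[],
            unmatched_tracks=[t.track_id for t in tracks],
            unmatched_detections=list(range(len(dets))),
        )
    order = sorted(range(len(tracks)),
                   key=lambda i: (-tracks[i].age, tracks[i].track_id))
    cost = np.ones((len(tracks), len(dets)))
    for row, ti in enumerate(order):
        trk = tracks[ti]
        pbox = trk.predicted_box()
        for j, det in enumerate(dets):
            if class_gated and det.class_label != trk.class_label:
                cost[row, j] = _GATED_COST
            else:
                cost[row, j] = 1.0 - iou(pbox, det.box)

    rows, cols = linear_sum_assignment(cost)
    matched_tracks: set[int] = set()
    matched_dets: set[int] = set()
    result = AssociationResult()
    for row, j in zip(rows, cols):
        if cost[row, j] > 1.0 - min_iou or cost[row, j] >= _GATED_COST:
            continue
        ti = order[row]
        result.matches.append((tracks[ti].track_id, j))
        matched_tracks.add(ti)
        matched_dets.add(j)
    result.unmatched_tracks = [
        tracks[i].track_id for i in range(len(tracks)) if i not in matched_tracks
    ]
    result.unmatched_detections = [
        j for j in range(len(dets)) if j not in matched_dets
    ]
    return result


def byte_associate(
    tracks: Sequence["Track"],
    dets: Sequence[Detection],
    config: "TrackerConfig",
) -> tuple[AssociationResult, AssociationResult, list[Detection]]:
    """Run the two-stage BYTE association for one frame.

    Returns (stage1, stage2, new_track_candidates).  Each stage's
    detection indices refer to its own ``detections`` list (the high band
    for stage 1, the low band for stage 2).  Unmatched low-band
    detections appear in no output and are discarded.
    """
    high, low, _ = partition_by_score(dets, config.tau_high, config.tau_low)

    stage1 = match(tracks, high, config.first_stage_min_iou,
                   class_gated=config.class_gated)

    # stage 2: only tracks that were actively tracked last frame retry
    # against the low band; lost tracks have no fresh box, so low-score
    # IoU against their drifting prediction is unreliable.
    by_id = {t.track_id: t for t in tracks}
    retry = [by_id[tid] for tid in stage1.unmatched_tracks
             if by_id[tid].is_tracked]
    stage2 = match(retry, low, config.second_stage_min_iou,
                   class_gated=config.class_gated)

    new_candidates = [
        high[j] for j in stage1.unmatched_detections
        if high[j].score >= config.new_track_score
    ]
    stage1.detections = high
    stage2.detections = low
    return stage1, stage2, new_candidates
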