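"""Per-frame tracking orchestration and the track lifecycle.

Each frame: predict every live track, run the two-stage BYTE association,
correct matched tracks, demote unmatched tracked tracks to lost, remove
lost tracks once they have gone more than ``max_lost`` frames (default
30) without a match, and start fresh tracks from unmatched high-score
detections.  Track ids are globally unique within a run and never reused.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .association import ConfigError, byte_associate
from .geometry import DEFAULT_LABELS, BoundingBox, Detection
from .kalman import KalmanBoxFilter, KalmanState, NoiseConfig


class StreamError(ValueError):
    """Raised for out-of-order or inconsistent frame streams."""


class TrackStatus(enum.Enum):
    TRACKED = "tracked"
    LOST = "lost"
    REMOVED = "removed"


@dataclass(frozen=True)
class TrackerConfig:
    """All tracker knobs.

    The score thresholds and IoU floors are reference BYTE-style defaults;
    ``max_lost`` is the 30-frame patience after which an unmatched track
    is discarded for good.
    """

    tau_high: float = 0.6
    tau_low: float = 0.1
    first_stage_min_iou: float = 0.2
    second_stage_min_iou: float = 0.5
    new_track_score: float = 0.6
    max_lost: int = 30
    min_hits: int = 1
    class_gated: bool = True
    state_convention: str = "paper"
    labels: tuple[str, ...] = DEFAULT_LABELS
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_low < self.tau_high <= 1.0):
            raise ConfigError(
                f"need 0 <= tau_low < tau_high <= 1; got {self.tau_low}, {self.tau_high}"
            )
        if self.max_lost < 1:
            raise ConfigError(f"max_lost must be >= 1, got {self.max_lost}")
        for name in ("first_stage_min_iou", "second_stage_min_iou"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class Track:
    """A persistent identity with class label, Kalman state and lifecycle."""

    track_id: int
    class_label: str
    state: KalmanState
    status: TrackStatus
    start_frame: int
    last_frame: int
    frames_since_update: int = 0
    hit_count: int = 1
    score: float = 0.0
    box: BoundingBox | None = None  # last observed box (prediction while lost)
    _kf: KalmanBoxFilter = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def age(self) -> int:
        return self.last_frame - self.start_frame + 1

    @property
    def is_tracked(self) -> bool:
        return self.status is TrackStatus.TRACKED

    def predicted_box(self) -> BoundingBox:
        return self._kf.box_from_mean(self.state.mean)


class Tracker:
    """Online multi-class tracker; feed frames in ascending order."""

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.config = config or TrackerConfig()
        self.kf = KalmanBoxFilter(self.config.noise, self.config.state_convention)
        self._ids = itertools.count(1)
        self.tracks: list[Track] = []      # live: tracked + lost
        self.removed: list[Track] = []
        self.last_frame: int | None = None
        self.ids_issued = 0

    # ------------------------------------------------------------------
    def step(self, frame_dets: Sequence[Detection],
             frame_index: int | None = None) -> list[Track]:
        """Process one frame; returns the tracks active in this frame."""
        frame = self._resolve_frame(frame_dets, frame_index)

        for trk in self.tracks:  # prediction continues while lost
            trk.state = self.kf.predict(trk.state)

        stage1, stage2, candidates = byte_associate(self.tracks, list(frame_dets), self.config)

        by_id = {t.track_id: t for t in self.tracks}
        matched_ids: set[int] = set()
        for stage in (stage1, stage2):
            for track_id, j in stage.matches:
                det = stage.detections[j]
                trk = by_id[track_id]
                trk.state = self.kf.correct(trk.state, det)
                trk.status = TrackStatus.TRACKED
                trk.frames_since_update = 0
                trk.hit_count += 1
                trk.last_frame = frame
                trk.box = det.box
                trk.score = det.score
                matched_ids.add(track_id)

        survivors: list[Track] = []
        for trk in self.tracks:
            if trk.track_id in matched_ids:
                survivors.append(trk)
                continue
            trk.frames_since_update += 1
            if trk.status is TrackStatus.TRACKED:
                trk.status = TrackStatus.LOST
            if trk.frames_since_update > self.config.max_lost:
                trk.status = TrackStatus.REMOVED
                self.removed.append(trk)
            else:
                trk.box = trk.predicted_box()
                survivors.append(trk)
        self.tracks = survivors

        for det in candidates:
            self.tracks.append(self._new_track(det, frame))

        self.last_frame = frame
        return [t for t in self.tracks
                if t.is_tracked and t.last_frame == frame
                and t.hit_count >= self.config.min_hits]

    def run(self, stream: Iterable[Sequence[Detection]]) -> "TrackHistory":
        """Run over a whole detection stream and record every frame.

        Frame indices come from the detections themselves; empty frames
        advance the clock by one (they still age lost tracks).
        """
        rows = []
        for frame_dets in stream:
            active = self.step(frame_dets)
            frame = self.last_frame
            for trk in sorted(active, key=lambda t: t.track_id):
                b = trk.box
                rows.append((frame, trk.track_id, trk.class_label,
                             b.x1, b.y1, b.x2, b.y2, trk.score,
                             trk.status.value))
        return TrackHistory(rows)

    # ------------------------------------------------------------------
    def _resolve_frame(self, frame_dets: Sequence[Detection],
                       frame_index: int | None) -> int:
        frames = {d.frame_index for d in frame_dets}
        if len(frames) > 1:
            raise StreamError(f"detections from multiple frames in one step: {sorted(frames)}")
        if frame_index is None:
            if frames:
                frame_index = frames.pop()
            elif self.last_frame is not None:
                frame_index = self.last_frame + 1
            else:
                frame_index = 0
        elif frames and frames != {frame_index}:
            raise StreamError(
                f"frame_index {frame_index} disagrees with detections ({frames.pop()})"
            )
        if self.last_frame is not None and frame_index <= self.last_frame:
            raise StreamError(
                f"out-of-order frame {frame_index} after {self.last_frame}"
            )
        return frame_index

    def _new_track(self, det: Detection, frame: int) -> Track:
        self.ids_issued += 1
        return Track(
            track_id=next(self._ids),
            class_label=det.class_label,
            state=self.kf.initiate(det),
            status=TrackStatus.TRACKED,
            start_frame=frame,
            last_frame=frame,
            score=det.score,
            box=det.box,
            _kf=self.kf,
        )


_HISTORY_COLUMNS = ("frame", "track_id", "class_label",
                    "x1", "y1", "x2", "y2", "score", "status")


class TrackHistory:
    """Per-frame record of all active tracks, backed by a DataFrame."""

    def __init__(self, rows: list[tuple]) -> None:
        self.df = pd.DataFrame(rows, columns=_HISTORY_COLUMNS)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TrackHistory) and self.df.equals(other.df)

    @property
    def track_ids(self) -> list[int]:
        return sorted(self.df["track_id"].unique().tolist())

    def frame_tracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        yield from self.df.groupby("frame", sort=True)


def run_tracker(stream: Iterable[Sequence[Detection]],
                config: TrackerConfig | None = None) -> TrackHistory:
    """Convenience wrapper: build a tracker, run the stream, return history."""
    return Tracker(config).run(stream)
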