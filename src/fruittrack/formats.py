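"""Readers and writers for detection streams, track histories and counts.

Two detection dialects are supported:

* ``mot_csv`` — one CSV per video in the ten-column MOT-Challenge layout
  ``frame,id,x,y,w,h,score,class_id,-1,-1`` with ``id = -1`` for raw
  detections and x,y the top-left corner in pixels.  Column 8 carries the
  class id (as MOT ground-truth files do; raw MOT detection files
  normally leave it -1), so third-party MOT tooling can read the output.
* ``yolo_txt`` — one text file per frame, rows
  ``class_id cx cy w h score`` with coordinates normalized to [0, 1];
  denormalization requires a declared frame size.

Track histories are written in the same mot_csv dialect with real ids;
count reports as (class, band, count, total) CSV or JSON with run
metadata.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .geometry import DEFAULT_LABELS, BoundingBox, Detection
from .roi import CountReport
from .tracker import TrackHistory

DEFAULT_CLASS_MAP: dict[int, str] = {i: lbl for i, lbl in enumerate(DEFAULT_LABELS)}


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


@dataclass(frozen=True)
class DetectionFileDialect:
    format: str = "mot_csv"                       # "mot_csv" | "yolo_txt"
    class_map: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    frame_size: tuple[int, int] | None = None     # (W, H); required for yolo_txt

    def __post_init__(self) -> None:
        if self.format not in ("mot_csv", "yolo_txt"):
            raise ValueError(f"unknown dialect format {self.format!r}")
        labels = list(self.class_map.values())
        if len(set(labels)) != len(labels):
            raise ValueError(f"class map must be bijective, got {self.class_map}")
        if self.format == "yolo_txt" and self.frame_size is None:
            raise ValueError("yolo_txt dialect requires an explicit frame_size")

    @property
    def label_to_id(self) -> dict[str, int]:
        return {lbl: i for i, lbl in self.class_map.items()}


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def read_detections(path: str | Path,
                    dialect: DetectionFileDialect | None = None
                    ) -> list[list[Detection]]:
    """Read a detection stream into per-frame lists (index 0 = frame 0).

    Frames with no detections come back as empty lists so the stream is
    dense up to the last frame seen.
    """
    dialect = dialect or DetectionFileDialect()
    if dialect.format == "mot_csv":
        dets = _read_mot_csv(Path(path), dialect)
    else:
        dets = _read_yolo_dir(Path(path), dialect)
    n_frames = max((d.frame_index for d in dets), default=-1) + 1
    stream: list[list[Detection]] = [[] for _ in range(n_frames)]
    for d in dets:
        stream[d.frame_index].append(d)
    return stream


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: bad number {token!r}") from None


def _read_mot_csv(path: Path, dialect: DetectionFileDialect) -> list[Detection]:
    dets: list[Detection] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 8:
                raise ParseError(f"{path}:{lineno}: expected >= 8 columns, got {len(row)}")
            frame = int(_parse_float(row[0], path, lineno))
            x, y, w, h = (_parse_float(t, path, lineno) for t in row[2:6])
            score = _parse_float(row[6], path, lineno)
            class_id = int(_parse_float(row[7], path, lineno))
            if class_id not in dialect.class_map:
                raise ParseError(f"{path}:{lineno}: unknown class id {class_id}")
            if w <= 0 or h <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive box size {w}x{h}")
            if frame < 0:
                raise ParseError(f"{path}:{lineno}: negative frame {frame}")
            dets.append(Detection(frame, BoundingBox.from_tlwh(x, y, w, h),
                                  min(max(score, 0.0), 1.0),
                                  dialect.class_map[class_id]))
    return dets


_YOLO_FRAME_RE = re.compile(r"(\d+)")


def _read_yolo_dir(path: Path, dialect: DetectionFileDialect) -> list[Detection]:
    if not path.is_dir():
        raise ParseError(f"{path}: yolo_txt input must be a directory of per-frame files")
    fw, fh = dialect.frame_size  # type: ignore[misc]
    dets: list[Detection] = []
    for file in sorted(path.glob("*.txt")):
        m = _YOLO_FRAME_RE.search(file.stem)
        if not m:
            raise ParseError(f"{file}: cannot infer frame index from filename")
        frame = int(m.group(1))
        with open(file) as handle:
            for lineno, line in enumerate(handle, start=1):
                tokens = line.split()
                if not tokens:
                    continue
                if len(tokens) < 6:
                    raise ParseError(f"{file}:{lineno}: expected 6 fields, got {len(tokens)}")
                class_id = int(_parse_float(tokens[0], file, lineno))
                if class_id not in dialect.class_map:
                    raise ParseError(f"{file}:{lineno}: unknown class id {class_id}")
                cx, cy, w, h, score = (_parse_float(t, file, lineno)
                                       for t in tokens[1:6])
                if w <= 0 or h <= 0:
                    raise ParseError(f"{file}:{lineno}: non-positive box size")
                dets.append(Detection(
                    frame,
                    BoundingBox.from_center(cx * fw, cy * fh, w * fw, h * fh),
                    min(max(score, 0.0), 1.0),
                    dialect.class_map[class_id]))
    return dets


def write_detections(stream: Sequence[Sequence[Detection]], path: str | Path,
                     dialect: DetectionFileDialect | None = None) -> None:
    dialect = dialect or DetectionFileDialect()
    label_to_id = dialect.label_to_id
    if dialect.format == "mot_csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for frame_dets in stream:
                for d in frame_dets:
                    x, y, w, h = d.box.to_tlwh()
                    writer.writerow([d.frame_index, -1,
                                     f"{x:.3f}", f"{y:.3f}", f"{w:.3f}", f"{h:.3f}",
                                     f"{d.score:.6f}", label_to_id[d.class_label],
                                     -1, -1])
        return
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    fw, fh = dialect.frame_size  # type: ignore[misc]
    for frame, frame_dets in enumerate(stream):
        lines = []
        for d in frame_dets:
            cx, cy = d.box.center
            lines.append(f"{label_to_id[d.class_label]} "
                         f"{cx / fw:.6f} {cy / fh:.6f} "
                         f"{d.box.width / fw:.6f} {d.box.height / fh:.6f} "
                         f"{d.score:.6f}")
        (out_dir / f"{frame:06d}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# track history / count reports / ground truth
# ---------------------------------------------------------------------------

def write_track_history(history: TrackHistory, path: str | Path,
                        dialect: DetectionFileDialect | None = None) -> None:
    """mot_csv layout with real track ids, sorted by (frame, id)."""
    label_to_id = (dialect or DetectionFileDialect()).label_to_id
    df = history.df.sort_values(["frame", "track_id"])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in df.itertuples(index=False):
            writer.writerow([int(row.frame), int(row.track_id),
                             f"{row.x1:.3f}", f"{row.y1:.3f}",
                             f"{row.x2 - row.x1:.3f}", f"{row.y2 - row.y1:.3f}",
                             f"{row.score:.6f}", label_to_id[row.class_label],
                             -1, -1])


def read_track_history(path: str | Path,
                       dialect: DetectionFileDialect | None = None) -> TrackHistory:
    dialect = dialect or DetectionFileDialect()
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 8:
                raise ParseError(f"{path}:{lineno}: expected >= 8 columns")
            frame, tid = int(row[0]), int(row[1])
            x, y, w, h = (float(t) for t in row[2:6])
            score, class_id = float(row[6]), int(float(row[7]))
            if class_id not in dialect.class_map:
                raise ParseError(f"{path}:{lineno}: unknown class id {class_id}")
            rows.append((frame, tid, dialect.class_map[class_id],
                         x, y, x + w, y + h, score, "tracked"))
    return TrackHistory(rows)


def write_count_report(report: CountReport, path: str | Path,
                       metadata: Mapping | None = None) -> None:
    """CSV at ``path`` plus a JSON twin at ``path.with_suffix('.json')``."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "band", "count", "total"])
        writer.writerows(report.to_rows())
    path.with_suffix(".json").write_text(report.to_json(**(metadata or {})))


def read_count_report(path: str | Path) -> dict[str, int]:
    """Per-class totals from a count-report CSV."""
    totals: dict[str, int] = {}
    df = pd.read_csv(path)
    for _, row in df.iterrows():
        totals[str(row["class"])] = int(row["total"])
    return totals


def read_truth_counts(path: str | Path) -> dict[tuple[str, str], int]:
    """Ground-truth count table: columns video_id, class, true_count."""
    df = pd.read_csv(path)
    required = {"video_id", "class", "true_count"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    return {(str(r["video_id"]), str(r["class"])): int(r["true_count"])
            for _, r in df.iterrows()}


def read_pred_counts(path: str | Path) -> dict[tuple[str, str], int]:
    """Automated count table: columns video_id, class, count."""
    df = pd.read_csv(path)
    required = {"video_id", "class", "count"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    return {(str(r["video_id"]), str(r["class"])): int(r["count"])
            for _, r in df.iterrows()}


def config_hash(config) -> str:
    """Stable short hash of any (nested) dataclass or mapping config."""
    def norm(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: norm(v) for k, v in asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {str(k): norm(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [norm(v) for v in obj]
        return obj
    payload = json.dumps(norm(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
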