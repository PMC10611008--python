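"""ROI-band counting.

A counting belt is a full-height vertical strip at a frame edge.  A track
is counted once per (band, class) the first time its box center lies
inside the strip; already-counted ids are remembered in per-band,
per-class lists so a target lingering in — or re-entering — the belt is
never double counted.  With two belts (one per frame side, filming the
two plant rows along an aisle) both sides are counted in a single pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .geometry import DEFAULT_LABELS, BoundingBox
from .tracker import Track, TrackHistory


@dataclass(frozen=True)
class ROIBand:
    """Vertical counting strip, expressed as fractions of frame width."""

    side: str                 # "left" or "right" (band identity in reports)
    x_min_frac: float
    x_max_frac: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_min_frac < self.x_max_frac <= 1.0):
            raise ValueError(
                f"band fractions must satisfy 0 <= min < max <= 1, "
                f"got [{self.x_min_frac}, {self.x_max_frac}]"
            )

    @classmethod
    def left(cls, frac: float = 0.15) -> "ROIBand":
        return cls("left", 0.0, frac)

    @classmethod
    def right(cls, frac: float = 0.15) -> "ROIBand":
        return cls("right", 1.0 - frac, 1.0)


def default_bands(mode: str = "double", side: str = "left",
                  frac: float = 0.15) -> tuple[ROIBand, ...]:
    """Band layout for double-side or single-side inspection."""
    if mode == "double":
        return (ROIBand.left(frac), ROIBand.right(frac))
    if mode == "single":
        return (ROIBand.left(frac) if side == "left" else ROIBand.right(frac),)
    raise ValueError(f"mode must be 'single' or 'double', got {mode!r}")


def center_in_band(box: BoundingBox, band: ROIBand, frame_width: float) -> bool:
    """Closed-interval test on the box center's x coordinate; y is ignored."""
    if frame_width <= 0:
        raise ValueError(f"frame_width must be positive, got {frame_width}")
    cx = box.center[0]
    return band.x_min_frac * frame_width <= cx <= band.x_max_frac * frame_width


@dataclass
class CountReport:
    """Final per-class totals plus the per-band breakdown."""

    per_band: dict[str, dict[str, int]]   # band side -> class -> count
    totals: dict[str, int]                # class -> count over all bands
    n_frames: int = 0

    def to_rows(self) -> list[tuple[str, str, int, int]]:
        """(class, band, count, total) rows for CSV export."""
        rows = []
        for cls, total in self.totals.items():
            for side, per_class in self.per_band.items():
                rows.append((cls, side, per_class.get(cls, 0), total))
        return rows

    def to_json(self, **metadata) -> str:
        return json.dumps(
            {"per_band": self.per_band, "totals": self.totals,
             "n_frames": self.n_frames, **metadata},
            indent=2, sort_keys=True)


class ROICounter:
    """Stateful per-frame counter over one or more bands.

    ``shared_lists`` makes all bands share one counted-id list per class
    (an id then contributes to at most one band); the default keeps
    per-band lists, so a target filmed in each of the two rows — an
    impossibility for a real plant, but possible for id reuse — would
    count once per band.
    """

    def __init__(self, bands: Sequence[ROIBand], frame_width: float,
                 labels: Sequence[str] = DEFAULT_LABELS,
                 shared_lists: bool = False) -> None:
        if frame_width <= 0:
            raise ValueError(f"frame_width must be positive, got {frame_width}")
        sides = [b.side for b in bands]
        if len(set(sides)) != len(sides):
            raise ValueError(f"band sides must be unique, got {sides}")
        self.bands = tuple(bands)
        self.frame_width = float(frame_width)
        self.labels = tuple(labels)
        self.shared_lists = shared_lists
        self._counted: dict[tuple[str, str], set[int]] = {}
        self.n_frames = 0
        self._reset_lists()

    def _reset_lists(self) -> None:
        self._counted = {
            (("shared" if self.shared_lists else b.side), cls): set()
            for b in self.bands for cls in self.labels
        }

    def _list_key(self, band: ROIBand, cls: str) -> tuple[str, str]:
        return ("shared" if self.shared_lists else band.side), cls

    # ------------------------------------------------------------------
    def update(self, frame_tracks: Iterable[Track]) -> dict[str, int]:
        """Ingest one frame of tracked-status tracks; returns running counts."""
        self.n_frames += 1
        for trk in frame_tracks:
            if not trk.is_tracked or trk.box is None:
                continue
            if trk.class_label not in self.labels:
                continue
            for band in self.bands:
                if center_in_band(trk.box, band, self.frame_width):
                    self._counted[self._list_key(band, trk.class_label)].add(
                        trk.track_id)
        return self.counts

    def update_from_rows(self, rows: Iterable[Mapping]) -> dict[str, int]:
        """Same as :meth:`update` but from track-history-style records."""
        self.n_frames += 1
        for row in rows:
            if row.get("status", "tracked") != "tracked":
                continue
            cls = row["class_label"]
            if cls not in self.labels:
                continue
            box = BoundingBox(row["x1"], row["y1"], row["x2"], row["y2"])
            for band in self.bands:
                if center_in_band(box, band, self.frame_width):
                    self._counted[self._list_key(band, cls)].add(int(row["track_id"]))
        return self.counts

    @property
    def counts(self) -> dict[str, int]:
        """Running per-class counts (sum over bands)."""
        out = {cls: 0 for cls in self.labels}
        for (_, cls), ids in self._counted.items():
            out[cls] += len(ids)
        return out

    def finalize(self) -> CountReport:
        """Return the final report and clear all counted-id lists."""
        per_band: dict[str, dict[str, int]] = {}
        for band in self.bands:
            key_side = "shared" if self.shared_lists else band.side
            per_band.setdefault(band.side, {})
            for cls in self.labels:
                ids = self._counted[(key_side, cls)]
                # under shared lists attribute everything to the first band once
                if self.shared_lists and band is not self.bands[0]:
                    per_band[band.side][cls] = 0
                else:
                    per_band[band.side][cls] = len(ids)
        totals = {cls: sum(pb.get(cls, 0) for pb in per_band.values())
                  for cls in self.labels}
        report = CountReport(per_band=per_band, totals=totals,
                             n_frames=self.n_frames)
        self._reset_lists()
        self.n_frames = 0
        return report


def count_history(history: TrackHistory, bands: Sequence[ROIBand],
                  frame_width: float, labels: Sequence[str] = DEFAULT_LABELS,
                  shared_lists: bool = False,
                  log_path: str | Path | None = None) -> CountReport:
    """Run the ROI counter over a finished track history.

    Optionally writes a per-frame running-count log (frame number plus the
    per-class counts shown in the on-screen display of the live tool).
    """
    counter = ROICounter(bands, frame_width, labels, shared_lists)
    log_rows = []
    for frame, group in history.frame_tracks():
        running = counter.update_from_rows(group.to_dict("records"))
        if log_path is not None:
            log_rows.append({"frame": int(frame), **running})
    if log_path is not None:
        import pandas as pd
        pd.DataFrame(log_rows, columns=["frame", *labels]).to_csv(
            log_path, index=False)
    return counter.finalize()
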