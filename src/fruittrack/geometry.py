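"""Bounding-box and detection data model.

Coordinates are continuous pixels, origin at the top-left corner of the
frame, y increasing downward.  The canonical stored form is the corner
form (x1, y1, x2, y2); center form and the Kalman observation form are
derived views.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

DEFAULT_LABELS: tuple[str, ...] = ("flower", "green_fruit", "red_fruit")


class BoxValidationError(ValueError):
    """Raised for degenerate or non-finite bounding boxes."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with strictly positive width and height."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(v):
                raise BoxValidationError(f"non-finite box coordinate: {v!r}")
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise BoxValidationError(
                f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2}) "
                "requires x2 > x1 and y2 > y1"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "BoundingBox":
        return cls(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)

    @classmethod
    def from_tlwh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        """From top-left + width/height (the MOT file convention)."""
        return cls(x, y, x + w, y + h)

    def to_tlwh(self) -> tuple[float, float, float, float]:
        return self.x1, self.y1, self.width, self.height


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 iff equal."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def to_observation(box: BoundingBox) -> tuple[float, float, float, float]:
    """Box -> (u, v, s, r): center, aspect ratio w/h, height."""
    u, v = box.center
    return u, v, box.width / box.height, box.height


def from_observation(u: float, v: float, s: float, r: float) -> BoundingBox:
    """Inverse of :func:`to_observation`."""
    if s <= 0 or r <= 0:
        raise BoxValidationError(f"observation requires s > 0 and r > 0, got s={s}, r={r}")
    return BoundingBox.from_center(u, v, s * r, r)


@dataclass(frozen=True)
class Detection:
    """One scored, class-labeled box observed in one frame."""

    frame_index: int
    box: BoundingBox
    score: float
    class_label: str = field(default=DEFAULT_LABELS[0])

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
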