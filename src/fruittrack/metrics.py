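"""Detection and counting evaluation.

Detection side: per-class precision P = TP/(TP+FP), recall R = TP/(TP+FN),
average precision AP = area under the precision envelope over recall, and
mAP = unweighted class mean.  A detection is correct when its IoU with an
unclaimed same-class ground-truth box is >= 0.5 (configurable).

Counting side: per-video counting accuracy
Pc = (1 - |Na - Nt| / Nt) x 100 %, its per-class average APc over videos,
and the cross-class mean mAPc.  Percentages are reported rounded half-up
to two decimals, matching how such tables are conventionally printed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import Detection, iou


class EvaluationError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as printed result tables use."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# counting metrics
# ---------------------------------------------------------------------------

def counting_accuracy(na: int, nt: int) -> float:
    """Pc = (1 - |Na - Nt| / Nt) x 100, to two decimals.

    Over- and under-counting are penalized symmetrically; Pc = 100 iff
    the automated count equals the truth, and can go negative when the
    error exceeds the true count.
    """
    if nt <= 0:
        raise EvaluationError(f"true count must be positive, got Nt={nt}")
    if na < 0:
        raise EvaluationError(f"automated count must be >= 0, got Na={na}")
    return round_half_up((1.0 - abs(na - nt) / nt) * 100.0)


def apc(pcs: Sequence[float]) -> float:
    """Per-class average counting precision: mean of per-video Pc values."""
    if len(pcs) == 0:
        raise EvaluationError("APc of an empty Pc list is undefined")
    return round_half_up(float(np.mean(pcs)))


def mapc(apcs: Sequence[float], n_classes: int | None = None) -> float:
    """Mean counting precision across classes (unweighted)."""
    if len(apcs) == 0:
        raise EvaluationError("mAPc of an empty APc list is undefined")
    if n_classes is not None and len(apcs) != n_classes:
        raise EvaluationError(
            f"expected {n_classes} per-class APc values, got {len(apcs)}")
    return round_half_up(float(np.mean(apcs)))


@dataclass
class CountEvalResult:
    """Automated-vs-true counts and the Pc/APc/mAPc statistics."""

    per_video: pd.DataFrame        # columns: video_id, class_label, na, nt, pc
    apc_per_class: dict[str, float]
    mapc: float

    def to_csv(self, path) -> None:
        summary = pd.DataFrame(
            [{"video_id": "APc", "class_label": cls, "na": "", "nt": "", "pc": v}
             for cls, v in self.apc_per_class.items()]
            + [{"video_id": "mAPc", "class_label": "", "na": "", "nt": "",
                "pc": self.mapc}])
        pd.concat([self.per_video, summary], ignore_index=True).to_csv(
            path, index=False)


def evaluate_counts(
    automated: Mapping[tuple[str, str], int],
    truth: Mapping[tuple[str, str], int],
) -> CountEvalResult:
    """Compare automated vs true counts keyed by (video_id, class_label).

    Videos/classes present in the truth but absent from the automated
    counts are scored with Na = 0.
    """
    rows = []
    for (video, cls), nt in sorted(truth.items()):
        na = automated.get((video, cls), 0)
        rows.append({"video_id": video, "class_label": cls,
                     "na": na, "nt": nt, "pc": counting_accuracy(na, nt)})
    if not rows:
        raise EvaluationError("no ground-truth counts to evaluate")
    per_video = pd.DataFrame(rows)
    apc_per_class = {
        cls: apc(group["pc"].tolist())
        for cls, group in per_video.groupby("class_label", sort=True)
    }
    return CountEvalResult(
        per_video=per_video,
        apc_per_class=apc_per_class,
        mapc=mapc(list(apc_per_class.values())),
    )


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

@dataclass
class DetectionEvalResult:
    per_class: pd.DataFrame    # columns: class_label, tp, fp, fn, p, r, ap
    mean_ap: float
    skipped_classes: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        df = self.per_class.copy()
        df["map"] = self.mean_ap
        df.to_csv(path, index=False)


def match_detections_to_truth(
    dets: Sequence[Detection],
    truths: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> pd.DataFrame:
    """Greedy score-descending matching of detections to ground truth.

    Within each (frame, class) group, detections claim at most one truth
    box each, highest score first; a claim requires IoU >= threshold.
    Returns one row per detection: class_label, score, tp (bool).
    Unclaimed truths are the false negatives (recoverable from counts).
    """
    truth_pool: dict[tuple[int, str], list[Detection]] = {}
    for t in truths:
        truth_pool.setdefault((t.frame_index, t.class_label), []).append(t)
    used: dict[tuple[int, str], list[bool]] = {
        k: [False] * len(v) for k, v in truth_pool.items()}

    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    tp_flags = [False] * len(dets)
    for i in order:
        d = dets[i]
        key = (d.frame_index, d.class_label)
        candidates = truth_pool.get(key, [])
        best_j, best_iou = -1, iou_threshold
        for j, t in enumerate(candidates):
            if used[key][j]:
                continue
            v = iou(d.box, t.box)
            if v >= best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            used[key][best_j] = True
            tp_flags[i] = True
    return pd.DataFrame({
        "class_label": [d.class_label for d in dets],
        "score": [d.score for d in dets],
        "tp": tp_flags,
    })


def average_precision(scores: Sequence[float], tp_flags: Sequence[bool],
                      n_truth: int, interpolation: str = "all_point") -> float:
    """Area under the precision envelope over recall.

    ``all_point`` integrates the exact monotone precision envelope
    (the modern convention); ``11_point`` samples recall at 0, 0.1, ..., 1.
    """
    if n_truth <= 0:
        raise EvaluationError("AP undefined with no positive ground truth")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_truth
    precision = cum_tp / (cum_tp + cum_fp)

    if interpolation == "11_point":
        ap = 0.0
        for r in np.linspace(0.0, 1.0, 11):
            mask = recall >= r
            ap += (precision[mask].max() if mask.any() else 0.0) / 11.0
        return float(ap)
    if interpolation != "all_point":
        raise ValueError(f"unknown interpolation {interpolation!r}")

    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):   # monotone precision envelope
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def mean_ap(aps: Sequence[float]) -> float:
    """Unweighted mean of per-class AP values (any common scale)."""
    if len(aps) == 0:
        raise EvaluationError("mAP of an empty AP list is undefined")
    return float(np.mean(aps))


def evaluate_detections(
    dets: Sequence[Detection],
    truths: Sequence[Detection],
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> DetectionEvalResult:
    """Full per-class P/R/AP and mAP for a detection stream vs ground truth."""
    matched = match_detections_to_truth(dets, truths, iou_threshold)
    n_truth_per_class: dict[str, int] = {}
    for t in truths:
        n_truth_per_class[t.class_label] = n_truth_per_class.get(t.class_label, 0) + 1

    classes = sorted(set(n_truth_per_class) | set(matched["class_label"]))
    rows, aps, skipped = [], [], []
    for cls in classes:
        sub = matched[matched["class_label"] == cls]
        tp = int(sub["tp"].sum())
        fp = int(len(sub) - tp)
        n_truth = n_truth_per_class.get(cls, 0)
        fn = n_truth - tp
        if n_truth == 0:
            warnings.warn(f"class {cls!r} has no ground truth; AP undefined, "
                          "excluded from mAP", stacklevel=2)
            skipped.append(cls)
            ap = np.nan
        else:
            ap = average_precision(sub["score"].tolist(), sub["tp"].tolist(),
                                   n_truth, interpolation)
            aps.append(ap)
        rows.append({"class_label": cls, "tp": tp, "fp": fp, "fn": fn,
                     "p": tp / (tp + fp) if tp + fp else np.nan,
                     "r": tp / (tp + fn) if tp + fn else np.nan,
                     "ap": ap})
    if not aps:
        raise EvaluationError("no class had positive ground truth")
    return DetectionEvalResult(
        per_class=pd.DataFrame(rows),
        mean_ap=mean_ap(aps),
        skipped_classes=skipped,
    )
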