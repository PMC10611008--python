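"""Synthetic inspection-scene generator.

Emulates a forward-moving camera pass along an orchard aisle filmed at
1920x1080 / 30 fps with the lens pointing down the row: plants on the two
sides appear near the frame edges and flow outward at roughly constant
pixel velocity (the camera advances at about 1 m/s).  Each target carries
one of three stage classes (flower / green_fruit / red_fruit), transits
the counting belt on its own side exactly once, and leaves the frame.

On top of the noiseless geometry the generator layers the failure modes a
real detector exhibits: frame-wise detection dropout, occlusion episodes
that suppress the confidence score into the low band (exercising the
second BYTE association stage), localization jitter, and short-lived
spurious false positives.  No images are rendered — the product is the
detection stream plus exact ground truth.

All random draws happen unconditionally in a fixed order (dropout
uniforms are always drawn; false-positive candidates are generated at a
fixed ceiling rate and thinned), so raising the noise rates with the same
seed only ever *adds* noise events.  This coupling makes the degradation
knob exactly monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .geometry import DEFAULT_LABELS, BoundingBox, Detection
from .roi import ROIBand, center_in_band, default_bands

#: typical detected box width ranges per stage class, pixels
_DEFAULT_SIZES: dict[str, tuple[float, float]] = {
    "flower": (55.0, 105.0),
    "green_fruit": (70.0, 120.0),
    "red_fruit": (80.0, 140.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Scene parameters; the defaults are the emulated filming conditions."""

    frame_width: int = 1920
    frame_height: int = 1080
    n_frames: int = 600
    frame_rate: int = 30
    labels: tuple[str, ...] = DEFAULT_LABELS
    targets_per_class_per_side: int = 5
    #: horizontal speed range, px/frame (~1 m/s camera advance at 30 fps)
    speed_range: tuple[float, float] = (6.0, 10.0)
    box_size_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SIZES))
    aspect_range: tuple[float, float] = (0.7, 1.3)
    band_frac: float = 0.15
    # --- noise ---
    dropout_rate: float = 0.05
    occlusion_rate: float = 0.3          # per-target probability of one episode
    occlusion_duration: tuple[int, int] = (3, 10)
    occlusion_score_range: tuple[float, float] = (0.05, 0.55)
    jitter_std: float = 2.0              # px, localization noise
    fp_rate: float = 0.5                 # expected false positives per frame
    fp_ceiling: float = 6.0              # thinning ceiling (fixed across sweeps)
    score_spread: float = 0.25           # true scores drawn from [1-spread, 1]
    fp_score_range: tuple[float, float] = (0.05, 0.65)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "occlusion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fp_rate < 0 or self.fp_ceiling < self.fp_rate:
            raise ValueError(
                f"need 0 <= fp_rate <= fp_ceiling, got {self.fp_rate}, {self.fp_ceiling}")
        if not 0.0 <= self.score_spread <= 1.0:
            raise ValueError(f"score_spread must lie in [0, 1], got {self.score_spread}")

    @classmethod
    def noiseless(cls, **overrides) -> "SimulationConfig":
        """The ideal-detector limit: detections equal truth with score 1."""
        base = dict(dropout_rate=0.0, occlusion_rate=0.0, jitter_std=0.0,
                    fp_rate=0.0, score_spread=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class TargetTrajectory:
    """Ground truth for one target: class, side, and its per-frame box."""

    target_id: int
    class_label: str
    side: str                       # which plant row / counting belt
    start_frame: int
    boxes: dict[int, BoundingBox]   # frame -> true box

    @property
    def frames(self) -> list[int]:
        return sorted(self.boxes)


@dataclass
class SimulationScene:
    """Generated trajectories, detections, and exact per-side class counts."""

    config: SimulationConfig
    trajectories: list[TargetTrajectory]
    detections: list[list[Detection]]            # index = frame
    detection_origins: list[list[int]]           # target_id, or -1 for FP
    true_counts: dict[str, dict[str, int]]       # side -> class -> count

    @property
    def total_true_counts(self) -> dict[str, int]:
        out = {cls: 0 for cls in self.config.labels}
        for per_class in self.true_counts.values():
            for cls, n in per_class.items():
                out[cls] += n
        return out

    def detection_stream(self) -> list[list[Detection]]:
        return self.detections


def _make_trajectory(tid: int, cls: str, side: str, cfg: SimulationConfig,
                     rng: np.random.Generator) -> TargetTrajectory:
    w_lo, w_hi = cfg.box_size_ranges.get(cls, (60.0, 120.0))
    w = rng.uniform(w_lo, w_hi)
    h = w / rng.uniform(*cfg.aspect_range)
    speed = rng.uniform(*cfg.speed_range)
    fw, fh = cfg.frame_width, cfg.frame_height
    # a target starts a third of the way in on its side and drifts outward,
    # crossing its counting belt before leaving the frame
    if side == "left":
        x0, vx = 0.32 * fw, -speed
        exit_x = -w
    else:
        x0, vx = 0.68 * fw, speed
        exit_x = fw + w
    transit = int(abs((exit_x - x0) / vx)) + 2
    latest_entry = max(1, cfg.n_frames - transit - 5)
    start = int(rng.integers(0, latest_entry))
    y0 = rng.uniform(0.15 * fh, 0.85 * fh - h)
    vy = rng.uniform(-0.3, 0.3)
    boxes: dict[int, BoundingBox] = {}
    for k in range(transit):
        frame = start + k
        if frame >= cfg.n_frames:
            break
        cx = x0 + vx * k
        cy = y0 + vy * k + h / 2.0
        if cx < -w or cx > fw + w:
            break
        boxes[frame] = BoundingBox.from_center(cx, cy, w, h)
    return TargetTrajectory(tid, cls, side, start, boxes)


def generate(config: SimulationConfig) -> SimulationScene:
    """Generate a scene; deterministic given the config (incl. its seed)."""
    ss = np.random.SeedSequence(config.seed)
    traj_ss, noise_ss, fp_ss = ss.spawn(3)

    # --- ground-truth trajectories (independent of noise settings) ---
    traj_rng = np.random.default_rng(traj_ss)
    trajectories: list[TargetTrajectory] = []
    tid = 0
    for side in ("left", "right"):
        for cls in config.labels:
            for _ in range(config.targets_per_class_per_side):
                trajectories.append(_make_trajectory(tid, cls, side, config, traj_rng))
                tid += 1

    # --- per-target detection noise, coupled for monotone degradation ---
    per_frame: list[list[Detection]] = [[] for _ in range(config.n_frames)]
    origins: list[list[int]] = [[] for _ in range(config.n_frames)]
    noise_children = noise_ss.spawn(max(len(trajectories), 1))
    for traj, child in zip(trajectories, noise_children):
        rng = np.random.default_rng(child)
        frames = traj.frames
        # occlusion episode parameters are always drawn
        u_occ = rng.uniform()
        occ_start_frac = rng.uniform()
        occ_dur = int(rng.integers(config.occlusion_duration[0],
                                   config.occlusion_duration[1] + 1))
        occ_active = u_occ < config.occlusion_rate and len(frames) > 0
        if frames:
            occ_begin = frames[0] + int(occ_start_frac * max(len(frames) - occ_dur, 1))
        for frame in frames:
            u_drop = rng.uniform()
            jitter = rng.normal(size=4)
            u_score = rng.uniform()
            u_occ_score = rng.uniform()
            if u_drop < config.dropout_rate:
                continue
            box = traj.boxes[frame]
            if config.jitter_std > 0:
                x1, y1, x2, y2 = (np.array([box.x1, box.y1, box.x2, box.y2])
                                  + config.jitter_std * jitter)
                if x2 - x1 < 2.0 or y2 - y1 < 2.0:
                    continue
                box = BoundingBox(x1, y1, x2, y2)
            occluded = occ_active and occ_begin <= frame < occ_begin + occ_dur
            if occluded:
                lo, hi = config.occlusion_score_range
                score = lo + u_occ_score * (hi - lo)
            else:
                score = 1.0 - u_score * config.score_spread
            per_frame[frame].append(Detection(frame, box, float(score),
                                              traj.class_label))
            origins[frame].append(traj.target_id)

    # --- false positives: ceiling-rate candidates, thinned ---
    fp_children = fp_ss.spawn(max(config.n_frames, 1))
    accept_p = config.fp_rate / config.fp_ceiling if config.fp_ceiling > 0 else 0.0
    for frame, child in enumerate(fp_children):
        rng = np.random.default_rng(child)
        n_cand = int(rng.poisson(config.fp_ceiling))
        for _ in range(n_cand):
            u_accept = rng.uniform()
            cx = rng.uniform(0, config.frame_width)
            cy = rng.uniform(0, config.frame_height)
            w = rng.uniform(30.0, 120.0)
            h = w / rng.uniform(*config.aspect_range)
            score = rng.uniform(*config.fp_score_range)
            cls = config.labels[int(rng.integers(len(config.labels)))]
            if u_accept >= accept_p:
                continue
            per_frame[frame].append(
                Detection(frame, BoundingBox.from_center(cx, cy, w, h),
                          float(score), cls))
            origins[frame].append(-1)

    # --- exact per-side class counts from the geometry ---
    bands = {b.side: b for b in default_bands("double", frac=config.band_frac)}
    true_counts = {side: {cls: 0 for cls in config.labels} for side in bands}
    for traj in trajectories:
        band = bands[traj.side]
        if any(center_in_band(b, band, config.frame_width)
               for b in traj.boxes.values()):
            true_counts[traj.side][traj.class_label] += 1

    return SimulationScene(config, trajectories, per_frame, origins, true_counts)


def degrade(scene: SimulationScene, level: float) -> SimulationScene:
    """Regenerate the scene with all noise rates scaled by (1 + level).

    Level 0 reproduces the scene unchanged; because of the coupled random
    draws, each higher level is a superset of the lower level's noise
    events (same seed).
    """
    if level < 0:
        raise ValueError(f"degradation level must be >= 0, got {level}")
    cfg = scene.config
    factor = 1.0 + level
    new_cfg = replace(
        cfg,
        dropout_rate=min(1.0, cfg.dropout_rate * factor),
        occlusion_rate=min(1.0, cfg.occlusion_rate * factor),
        fp_rate=min(cfg.fp_ceiling, cfg.fp_rate * factor),
    )
    return generate(new_cfg)


def count_missing_detections(scene: SimulationScene) -> int:
    """True target-frames with no emitted detection (dropout + shrink loss)."""
    emitted: dict[int, set[int]] = {}
    for frame, ids in enumerate(scene.detection_origins):
        for tid in ids:
            if tid >= 0:
                emitted.setdefault(tid, set()).add(frame)
    missing = 0
    for traj in scene.trajectories:
        missing += len(set(traj.frames) - emitted.get(traj.target_id, set()))
    return missing
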