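# Methods

## Problem setting

An inspection camera moves along an orchard aisle (~1 m/s, 30 fps,
1920×1080), filming the plant rows on both sides. An external detector
emits per-frame bounding boxes with confidence scores and one of three
stage classes: `flower`, `green_fruit`, `red_fruit`. The package turns
that stream into per-class counts and evaluates both the detections and
the counts. Everything downstream of the detector is in scope; the
detector itself is not — only its output format is modeled.

## Motion model

Each track is a linear-Gaussian state
`x = [u, v, s, r, u̇, v̇, ṡ]ᵀ` with a constant-velocity transition:
`u += u̇`, `v += v̇`, `s += ṡ` per frame, `r` constant. Units are pixels
and pixels/frame; the time step is fixed at one frame (frame-rate-aware
dynamics are out of scope). Two conventions for the shape components are
supported:

* `paper` (default): `s` = aspect ratio `w/h` (with rate term),
  `r` = height (constant);
* `sort`: `s` = area (with rate term), `r` = aspect ratio (constant).

Both share the same transition matrix; only the box↔observation map and
noise scaling differ. The class label is carried as an immutable
categorical **outside** the 7-dimensional Gaussian: a discrete label
cannot participate in a linear-Gaussian update, and its only dynamical
role is gating association, so it has no noise and no dynamics and can
never change after initialization.

Noise magnitudes are height-scaled (position-like stds ∝ `r` with weight
1/20, velocity stds ∝ `r` with weight 1/160, fixed absolute stds for the
dimensionless aspect terms), so a 40 px fruit and a 400 px one are
filtered consistently. Velocities initialize to zero with inflated
initial velocity variance. The measurement update uses the Joseph form,
covariances are re-symmetrized after every step, and `s`, `r` are
clamped positive after correction; a property test drives random
predict/correct sequences and asserts the covariance stays symmetric
PSD. With a near-noiseless model (measurement std → 0, velocity process
noise ≫ position process noise) the filter is an essentially deadbeat
observer: on noiseless constant-velocity input its one-step prediction
error falls below 10⁻⁶ px after a few frames, which is the package's
exactness check; under the default noise weights convergence is
geometric instead (by design — those weights expect jittery input).

## Association

Per frame, detections are split at `τ_high = 0.6` and `τ_low = 0.1`
(closed lower edges: a score equal to a threshold joins the upper band).
Stage 1 assigns high-band detections to all live tracks — tracked *and*
lost — by solving a rectangular linear assignment on cost `1 − IoU`
(scipy's Hungarian solver); pairs with different classes get a
prohibitive sentinel cost, which is equivalent to solving one problem
per class but keeps a single bookkeeping path and degrades gracefully
when gating is disabled for ablation. Assignments under the stage-1 IoU
floor (0.2) are demoted to unmatched. Stage 2 lets tracks that were
actively tracked last frame retry against the low band at a stricter
floor (0.5); lost tracks sit stage 2 out, since matching a drifting
prediction to a low-confidence box is how phantom revivals happen.
Unmatched high-band detections with score ≥ `τ_high` found new tracks;
unmatched low-band detections are discarded. All four thresholds are
package defaults in the reference-BYTE style — the source workflow does
not specify them numerically — and all are exposed in `TrackerConfig`.
Assignment ties are broken deterministically (older track, then lower
id) so identical inputs give byte-identical output.

## Track lifecycle

New tracks are emitted as `tracked` from their first frame — the
described workflow has no probation period — with an optional SORT-style
`min_hits` knob (default 1) for users who want one. A track unmatched in
a frame becomes `lost`; prediction continues while lost so the gate
follows the target's extrapolated motion. When `frames_since_update`
exceeds `max_lost = 30` — i.e. re-association is still possible *within*
30 frames, and forced removal happens on the 31st — the track becomes
`removed` and its id is never reused. Ids are global across classes,
starting at 1.

## Counting

A counting belt is a full-height vertical strip; the default layout puts
one 15 %-of-width belt at each frame edge (the two belts film the two
plant rows; single-side mode is the same machinery with one belt). Belt
width is a package default: the workflow shows belts but gives no
number, and at ~8 px/frame a 288 px belt is crossed over ~36 frames,
plenty to catch a tracked target. The membership test is a closed
interval on the box center's x. Only `tracked`-status tracks count — a
lost track's predicted box is not a confirmed observation. Counted-id
lists are per (belt, class); an id appearing in both belts counts once
per belt (a real plant cannot cross the aisle, so that case can only be
id reuse, which the tracker forbids — a `shared_lists` toggle collapses
the lists for users who prefer global uniqueness). Counts are monotone
until `finalize()`, which reports per-class totals plus the per-belt
breakdown and clears the lists.

## Metrics

Detection: greedy score-descending one-to-one matching within (frame,
class) at IoU ≥ 0.5; P, R per class; AP by all-point interpolation (the
exact area under the monotone precision envelope; an 11-point variant is
available by flag); mAP the unweighted class mean. Counting:
`Pc = (1 − |Na − Nt|/Nt) × 100 %` — the absolute value makes over- and
undercounting symmetric penalties, the only reading consistent with the
published per-video figures; `APc` the per-class mean over videos;
`mAPc` the cross-class mean. Reported percentages are rounded half-up to
two decimals, as result tables print them. Known limit: with printed
per-video figures, `APc` recomputed from raw counts can differ from a
published class average in the second decimal depending on intermediate
rounding; the package always computes from what it is given and does not
chase any particular rounding chain.

## Simulator

`SimulationConfig` defaults define the emulated filming conditions:
1920×1080 at 30 fps, targets entering on a schedule and translating
horizontally outward at 6–10 px/frame (the pixel-space effect of ~1 m/s
camera advance on side-row plants), class-typical box sizes
(55–140 px), and tens of targets per class per scene. Each target
belongs to one side and transits exactly that side's belt once, so true
per-(side, class) counts are known by construction and are also verified
geometrically. Occlusion is modeled as confidence suppression into
[0.05, 0.55] for a 3–10-frame episode (optionally nothing else — it is
the score dip, not pixel overlap, that exercises stage 2); detector
imperfection as 5 % frame-wise dropout, 2 px localization jitter, true
scores in [0.75, 1], and Poisson false positives (0.5/frame, scores in
[0.05, 0.65] so a small fraction clears the new-track threshold, as
confident detector hallucinations occasionally do). Under these defaults
at study scale (30 targets/class, 600 frames) the pipeline lands at
mAPc ≈ 92 %, inside the 91.9–97.7 % per-class band reported for real
orchard videos — evidence the noise levels are of realistic magnitude,
not a claim of equivalence.

What the simulator does *not* emulate: appearance (no images exist, so
nothing tests appearance-based re-identification — irrelevant here since
the tracker uses none), geometric occlusion between box pairs,
perspective growth of boxes, camera shake, class-confusion errors by the
detector, and night-time-specific artifacts beyond what the degradation
knob produces. Passing tests therefore demonstrate correct tracking,
counting and metric logic under realistic *kinematics and score
statistics*, not detector performance on real imagery.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawns, with every draw made unconditionally in a fixed order: dropout
uniforms are drawn whether or not a frame drops, and false-positive
candidates are generated at a fixed ceiling rate (6/frame) and thinned
to the configured rate. Consequently `degrade(scene, level)` — which
multiplies dropout/occlusion/false-positive rates by (1 + level) and
regenerates with the same seed — produces a noise-event superset of the
lower level: missing detections are exactly monotone in the level, and
mean counting precision falls smoothly (a 20-seed sweep at scene sizes
of 4 targets/class drops from mAPc ≈ 70 to below 0 across levels 0–3;
small scenes make Pc coarse, which is intended for stress testing, not a
statement about field accuracy).

## Numerical and design choices

* IoU of disjoint boxes is exactly 0; degenerate (zero-area) boxes are
  rejected at construction, so IoU never divides by zero.
* The Hungarian solver runs on a dense cost matrix with a 10⁶ sentinel
  for gated pairs; any sentinel assignment is filtered out afterwards,
  so the result is identical to per-class subproblems.
* Problem sizes in the test suite (600-frame scenes, ≤ 20 seeds per
  sweep, 150-frame scenes for the 100-scene invariant sweep) were chosen
  so the full suite runs in about a minute on one core while keeping
  tens of targets per class — the scale of a real per-video count table.
* Streams are dense per-frame lists; an empty list is a frame with no
  detections and still ages lost tracks. Skipping frame indices in
  direct `step()` calls is allowed but does not fast-forward the lost
  counter (the counter is per processed frame).
* File I/O round-trips at 3-decimal pixel precision (MOT CSV) and
  6-decimal normalized precision (YOLO text); parsing rejects unknown
  class ids, non-positive sizes and malformed numbers with file:line
  context, and is locale-independent.

## Known limitations

* No appearance features: after the 30-frame patience a returning target
  is necessarily a new id (by design, matching the source workflow).
* Counting accuracy is identity-based; systematic detector bias that
  never crosses a belt (e.g. a class never detected) shows up as Pc = 0
  for that class, not as an error message.
* The per-frame lost-counter semantics mean sparse streams with frame
  gaps age tracks in steps, not wall-clock frames.
* `Pc` can be negative when the count error exceeds the true count; APc
  averages whatever Pc produces, matching the published formula rather
  than clamping.
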