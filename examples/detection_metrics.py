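"""Detection evaluation: per-class precision, recall, AP and mAP.

A simulated scene provides ground-truth boxes; a degraded copy of its
detection stream plays the role of an imperfect detector.  A detection
counts as correct when it overlaps a same-class truth box with
IoU >= 0.5 (one-to-one, highest score first); AP is the area under the
precision envelope over recall.
"""

from fruittrack import SimulationConfig, evaluate_detections, generate

truth_scene = generate(SimulationConfig.noiseless(
    n_frames=300, targets_per_class_per_side=4, seed=7))
noisy_scene = generate(SimulationConfig(
    n_frames=300, targets_per_class_per_side=4, seed=7,
    dropout_rate=0.1, jitter_std=3.0, fp_rate=1.0))

truths = [d for frame in truth_scene.detections for d in frame]
dets = [d for frame in noisy_scene.detections for d in frame]

result = evaluate_detections(dets, truths)
print(result.per_class.to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"))
print(f"mAP = {result.mean_ap:.4f}")
# P = TP/(TP+FP) is how clean the detections are, R = TP/(TP+FN) how
# complete; AP integrates the trade-off over the score sweep, and mAP
# averages it across the three stage classes.
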