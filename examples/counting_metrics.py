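"""Counting evaluation: Pc per video, APc per class, mAPc overall.

Inputs are automated/true count pairs for four test videos (the worked
figures from the published evaluation of this counting pipeline).
Pc = (1 - |Na - Nt| / Nt) x 100%; APc averages Pc over videos; mAPc
averages APc over the three stage classes.
"""

from fruittrack import evaluate_counts

VIDEOS = ("v1", "v2", "v3", "v4")
AUTOMATED = {
    "flower": (64, 95, 13, 15),
    "green_fruit": (43, 51, 49, 79),
    "red_fruit": (18, 15, 70, 103),
}
TRUE = {
    "flower": (66, 95, 13, 16),
    "green_fruit": (53, 52, 50, 80),
    "red_fruit": (18, 18, 77, 110),
}

pred = {(v, cls): n for cls, row in AUTOMATED.items() for v, n in zip(VIDEOS, row)}
truth = {(v, cls): n for cls, row in TRUE.items() for v, n in zip(VIDEOS, row)}

result = evaluate_counts(pred, truth)
print(result.per_video.to_string(index=False))
for cls, v in result.apc_per_class.items():
    print(f"APc[{cls}] = {v:.2f}%")
print(f"mAPc = {result.mapc:.2f}%")
# A perfect count gives Pc = 100; the flower class averages 97.68% over
# the four videos, and mAPc summarizes all classes in one figure.
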