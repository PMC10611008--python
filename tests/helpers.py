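"""Shared scenario-construction helpers."""

from fruittrack import BoundingBox, Detection


def make_det(frame=0, x=100.0, y=100.0, w=40.0, h=50.0, score=0.9,
             cls="flower"):
    """A detection given its top-left corner and size."""
    return Detection(frame, BoundingBox.from_tlwh(x, y, w, h), score, cls)


def moving_target_stream(n_frames, vx=5.0, x0=50.0, y0=200.0, w=40.0, h=50.0,
                         cls="flower", score_fn=None, missing=()):
    """Per-frame detection lists for one constant-velocity target.

    ``score_fn(frame) -> score`` customizes confidence; frames listed in
    ``missing`` emit no detection.
    """
    stream = []
    for k in range(n_frames):
        if k in missing:
            stream.append([])
            continue
        score = score_fn(k) if score_fn else 0.9
        stream.append([make_det(frame=k, x=x0 + vx * k, y=y0, w=w, h=h,
                                score=score, cls=cls)])
    return stream
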