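"""Axis-aligned box arithmetic shared by the pipeline and the evaluator.

Boxes are 0-based half-open pixel tuples ``(x_min, y_min, x_max, y_max)``.
"""

from __future__ import annotations

Box = tuple[float, float, float, float]


def box_area(box: Box) -> float:
    return max(0.0, box[2] - box[0]) * max(0.0, box[3] - box[1])


def intersection_area(a: Box, b: Box) -> float:
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return max(0.0, w) * max(0.0, h)


def iou(a: Box, b: Box) -> float:
    """Intersection over union; 0 when either box is degenerate."""
    inter = intersection_area(a, b)
    union = box_area(a) + box_area(b) - inter
    return inter / union if union > 0 else 0.0
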