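"""Two-level evaluation of PHI detection: case level and instance level.

*Case level* asks, per image: does the image contain at least one PHI
imprint (or one of a given category), and did the pipeline flag it? This is
the flagging-system view. *Instance level* asks, per imprint: was each
individual PHI imprint localized (IoU against ground truth) and typed
correctly? This is the redaction view, where every missed instance is a
potential leak.

Instance matching is greedy one-to-one by descending IoU with a threshold
(default 0.5); ground-truth boxes in evaluation-style datasets are disjoint,
where greedy matching coincides with optimal assignment. Predictions
without coordinates (the end-to-end setup) cannot be evaluated at instance
level and are rejected explicitly. Failed pipeline images are scored as
predicting nothing — conservatively inflating false negatives — because the
pipeline error rate is reported separately.

Metrics are precision, recall, and raw FP/FN/TP counts, overall and per PHI
category, with mean ± sample standard deviation across repeated runs
(counts are averaged, so fractional means are expected).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import (AggregationError, AlignmentError,
                     InstanceEvalUnavailableError)
from .geometry import Box, iou
from .pipeline import PipelineOutput
from .simulator import ImprintLabel
from .taxonomy import PHI_CATEGORY_IDS

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_instances",
    "case_level_eval",
    "instance_level_eval",
    "aggregate_runs",
    "evaluate_all_scopes",
    "reports_to_dataframe",
    "write_reports",
]

OVERALL_SCOPE = "phi"


@dataclass
class MatchResult:
    """One-to-one box matching outcome for a single image."""

    pairs: list[tuple[int, int, float]]  # (gt index, pred index, IoU)
    unmatched_gt: list[int]
    unmatched_pred: list[int]


@dataclass
class EvalReport:
    """Precision/recall/FP/FN at one level and scope.

    ``precision``/``recall`` are ``None`` when their denominator is zero
    (reported as absent, not as 0 or 1). For multi-run aggregates
    (``n_runs > 1``) counts are arithmetic means and ``mean``/``std`` hold
    per-metric statistics (sample standard deviation, ddof=1).
    """

    level: str
    scope: str
    tp: float
    fp: float
    fn: float
    precision: Optional[float]
    recall: Optional[float]
    n_runs: int = 1
    mean: Optional[dict] = None
    std: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {"level": self.level, "scope": self.scope, "tp": self.tp,
             "fp": self.fp, "fn": self.fn, "precision": self.precision,
             "recall": self.recall, "n_runs": self.n_runs}
        if self.std is not None:
            d["std"] = self.std
        return d


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def _make_report(level: str, scope: str, tp: float, fp: float,
                 fn: float) -> EvalReport:
    return EvalReport(level=level, scope=scope, tp=tp, fp=fp, fn=fn,
                      precision=_ratio(tp, tp + fp), recall=_ratio(tp, tp + fn))


def match_instances(gt_boxes: Sequence[Box], pred_boxes: Sequence[Box],
                    iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching by descending IoU; pairs below the
    threshold are rejected."""
    candidates = []
    for gi, g in enumerate(gt_boxes):
        for pi, p in enumerate(pred_boxes):
            value = iou(g, p)
            if value >= iou_threshold:
                candidates.append((value, gi, pi))
    # stable deterministic order: IoU desc, then gt and pred index asc
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    pairs = []
    for value, gi, pi in candidates:
        if gi in used_gt or pi in used_pred:
            continue
        pairs.append((gi, pi, value))
        used_gt.add(gi)
        used_pred.add(pi)
    unmatched_gt = [i for i in range(len(gt_boxes)) if i not in used_gt]
    unmatched_pred = [i for i in range(len(pred_boxes)) if i not in used_pred]
    return MatchResult(pairs=pairs, unmatched_gt=unmatched_gt,
                       unmatched_pred=unmatched_pred)


def _check_alignment(gt: Mapping, preds: Mapping) -> None:
    if set(gt) != set(preds):
        missing = sorted(set(gt) ^ set(preds))[:5]
        raise AlignmentError(
            f"ground truth and predictions cover different image ids "
            f"(first differing: {missing})")


def _gt_positive(labels: Sequence[ImprintLabel], scope: str) -> bool:
    if scope == OVERALL_SCOPE:
        return any(l.phi_class for l in labels)
    return any(l.sub_class == scope for l in labels)


def _pred_positive(output: PipelineOutput, scope: str) -> bool:
    if output.failed:
        return False
    if scope == OVERALL_SCOPE:
        return any(item.analysis.is_phi_type for item in output.items)
    return any(item.analysis.type == scope for item in output.items)


def case_level_eval(gt: Mapping[str, Sequence[ImprintLabel]],
                    preds: Mapping[str, PipelineOutput],
                    scope: str = OVERALL_SCOPE) -> EvalReport:
    """Image-level binary classification of PHI presence.

    Ground truth is positive iff the image has ≥1 PHI imprint (of the given
    category under a category scope); the prediction is positive iff ≥1
    analysis result carries a PHI type (that category, respectively).
    """
    _check_alignment(gt, preds)
    tp = fp = fn = 0
    for image_id in gt:
        truth = _gt_positive(gt[image_id], scope)
        predicted = _pred_positive(preds[image_id], scope)
        if truth and predicted:
            tp += 1
        elif not truth and predicted:
            fp += 1
        elif truth and not predicted:
            fn += 1
    return _make_report("case", scope, tp, fp, fn)


def _instance_sets(labels: Sequence[ImprintLabel], output: PipelineOutput,
                   scope: str) -> tuple[list[Box], list[Box]]:
    if scope == OVERALL_SCOPE:
        gt_boxes = [tuple(l.bbox) for l in labels if l.phi_class]
        pred_boxes = [item.region.bbox for item in output.items
                      if item.analysis.is_phi_type]
    else:
        gt_boxes = [tuple(l.bbox) for l in labels if l.sub_class == scope]
        pred_boxes = [item.region.bbox for item in output.items
                      if item.analysis.type == scope]
    return gt_boxes, pred_boxes


def instance_level_eval(gt: Mapping[str, Sequence[ImprintLabel]],
                        preds: Mapping[str, PipelineOutput],
                        iou_threshold: float = 0.5,
                        scope: str = OVERALL_SCOPE) -> EvalReport:
    """Dataset-level instance matching: every PHI imprint must be localized
    (IoU ≥ threshold) by a prediction of agreeing type.

    Raises :class:`InstanceEvalUnavailableError` when any non-failed
    prediction lacks coordinates (end-to-end outputs carry none).
    """
    _check_alignment(gt, preds)
    for image_id, output in preds.items():
        if not output.failed and any(item.region is None
                                     for item in output.items):
            raise InstanceEvalUnavailableError(
                f"predictions for {image_id} carry no coordinates; "
                "instance-level evaluation is unavailable for this setup")
    tp = fp = fn = 0
    for image_id in gt:
        output = preds[image_id]
        labels = gt[image_id]
        if output.failed:
            gt_boxes, _ = _instance_sets(labels, PipelineOutput(
                image_id=image_id, setup=output.setup), scope)
            fn += len(gt_boxes)
            continue
        gt_boxes, pred_boxes = _instance_sets(labels, output, scope)
        match = match_instances(gt_boxes, pred_boxes, iou_threshold)
        tp += len(match.pairs)
        fn += len(match.unmatched_gt)
        fp += len(match.unmatched_pred)
    return _make_report("instance", scope, tp, fp, fn)


_METRICS = ("precision", "recall", "tp", "fp", "fn")


def aggregate_runs(reports: Sequence[EvalReport]) -> EvalReport:
    """Mean ± sample standard deviation of each metric over repeated runs.

    Counts are averaged, so fractional means are expected. Metrics that are
    absent (zero denominator) in a run are skipped; a metric absent in every
    run stays absent. A single run passes through with no ``std``.
    """
    if not reports:
        raise AggregationError("no reports to aggregate")
    level, scope = reports[0].level, reports[0].scope
    if any(r.level != level or r.scope != scope for r in reports):
        raise AggregationError("cannot aggregate reports with mixed level/scope")
    if len(reports) == 1:
        return reports[0]
    mean: dict[str, Optional[float]] = {}
    std: dict[str, Optional[float]] = {}
    for metric in _METRICS:
        values = [getattr(r, metric) for r in reports
                  if getattr(r, metric) is not None]
        if not values:
            mean[metric] = std[metric] = None
            continue
        m = sum(values) / len(values)
        mean[metric] = m
        std[metric] = (math.sqrt(sum((v - m) ** 2 for v in values)
                                 / (len(values) - 1))
                       if len(values) > 1 else 0.0)
    return EvalReport(level=level, scope=scope,
                      tp=mean["tp"], fp=mean["fp"], fn=mean["fn"],
                      precision=mean["precision"], recall=mean["recall"],
                      n_runs=len(reports), mean=mean, std=std)


def evaluate_all_scopes(gt: Mapping[str, Sequence[ImprintLabel]],
                        preds: Mapping[str, PipelineOutput],
                        level: str = "case",
                        iou_threshold: float = 0.5) -> list[EvalReport]:
    """Overall-PHI plus one report per PHI category, at one level."""
    scopes = (OVERALL_SCOPE,) + PHI_CATEGORY_IDS
    if level == "case":
        return [case_level_eval(gt, preds, scope) for scope in scopes]
    if level == "instance":
        return [instance_level_eval(gt, preds, iou_threshold, scope)
                for scope in scopes]
    raise AggregationError(f"unknown evaluation level {level!r}")


def reports_to_dataframe(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Rows shaped like the benchmark tables: level, scope,
    precision (FP), recall (FN), with std columns for aggregates."""
    rows = []
    for r in reports:
        row = {"level": r.level, "scope": r.scope, "precision": r.precision,
               "fp": r.fp, "recall": r.recall, "fn": r.fn, "tp": r.tp,
               "n_runs": r.n_runs}
        if r.std:
            for metric in _METRICS:
                row[f"{metric}_std"] = r.std.get(metric)
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(reports: Sequence[EvalReport], csv_path=None,
                  json_path=None) -> None:
    frame = reports_to_dataframe(reports)
    if csv_path is not None:
        frame.to_csv(Path(csv_path), index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([r.to_dict() for r in reports], indent=1))
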