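import itertools

import numpy as np
import pytest

from phimprint import evaluation as ev
from phimprint import pipeline as pl
from phimprint.errors import (AggregationError, AlignmentError,
                              InstanceEvalUnavailableError)
from phimprint.evaluation import (EvalReport, aggregate_runs, case_level_eval,
                                  instance_level_eval, match_instances)
from phimprint.geometry import iou
from phimprint.pipeline import (AnalysisResult, PipelineItem, PipelineOutput,
                                SetupId, TextRegion)
from phimprint.simulator import ImprintLabel


def pred_output(image_id, typed_boxes, setup=SetupId.setup1, failed=False):
    """Build a PipelineOutput from (type, bbox) pairs; bbox None = no coords."""
    items = [PipelineItem(
        analysis=AnalysisResult(type=t, raw_text="", reason="", language="en"),
        region=None if b is None else TextRegion(bbox=tuple(b)))
        for t, b in typed_boxes]
    return PipelineOutput(image_id=image_id, setup=setup, items=items,
                          failed=failed)


def optimal_match_count(gt_boxes, pred_boxes, threshold):
    """Exhaustive maximum one-to-one matching (oracle for ≤6 boxes)."""
    eligible = [[iou(g, p) >= threshold for p in pred_boxes] for g in gt_boxes]
    best = 0
    n_pred = len(pred_boxes)
    for k in range(min(len(gt_boxes), n_pred), 0, -1):
        for gt_subset in itertools.combinations(range(len(gt_boxes)), k):
            for pred_perm in itertools.permutations(range(n_pred), k):
                if all(eligible[g][p] for g, p in zip(gt_subset, pred_perm)):
                    return k
    return best


class TestMatchInstances:
    def test_identical_sets_fully_matched(self):
        boxes = [(0, 0, 10, 10), (20, 20, 40, 40)]
        result = match_instances(boxes, boxes, 0.5)
        assert len(result.pairs) == 2
        assert all(v == 1.0 for *_, v in result.pairs)
        assert result.unmatched_gt == [] and result.unmatched_pred == []

    def test_iou_one_third_threshold_boundary(self):
        gt, pred = [(0, 0, 10, 10)], [(5, 0, 15, 10)]
        assert iou(gt[0], pred[0]) == pytest.approx(1 / 3)
        assert len(match_instances(gt, pred, 1 / 3).pairs) == 1
        assert len(match_instances(gt, pred, 0.34).pairs) == 0

    def test_sum_conservation(self, rng):
        for _ in range(50):
            gt = [tuple(b) for b in _random_boxes(rng, 5)]
            pred = [tuple(b) for b in _random_boxes(rng, 5)]
            m = match_instances(gt, pred, 0.5)
            assert len(m.pairs) + len(m.unmatched_gt) == len(gt)
            assert len(m.pairs) + len(m.unmatched_pred) == len(pred)

    def test_threshold_monotonicity(self, rng):
        for _ in range(30):
            gt = _disjoint_boxes(rng, 4)
            pred = _jitter(rng, gt, extra=2)
            previous = None
            for thr in (0.9, 0.7, 0.5, 0.3, 0.1):
                tp = len(match_instances(gt, pred, thr).pairs)
                if previous is not None:
                    assert tp >= previous
                previous = tp

    def test_greedy_equals_exhaustive_on_disjoint_gt(self, rng):
        """On non-overlapping ground truth at IoU 0.5 greedy one-to-one
        matching attains the optimal assignment exactly."""
        for _ in range(200):
            gt = _disjoint_boxes(rng, int(rng.integers(0, 7)))
            pred = _jitter(rng, gt, extra=int(rng.integers(0, 3)))
            greedy = len(match_instances(gt, pred, 0.5).pairs)
            assert greedy == optimal_match_count(gt, pred, 0.5)


def _random_boxes(rng, n):
    boxes = []
    for _ in range(n):
        x, y = rng.integers(0, 80, size=2)
        w, h = rng.integers(5, 30, size=2)
        boxes.append((int(x), int(y), int(x + w), int(y + h)))
    return boxes


def _disjoint_boxes(rng, n):
    """Non-overlapping boxes on a grid (evaluation-style ground truth)."""
    cells = rng.choice(16, size=n, replace=False)
    boxes = []
    for c in cells:
        cx, cy = (int(c) % 4) * 50, (int(c) // 4) * 50
        w, h = int(rng.integers(20, 45)), int(rng.integers(20, 45))
        boxes.append((cx, cy, cx + w, cy + h))
    return boxes


def _jitter(rng, gt, extra=0):
    """Predictions: jittered copies of gt plus unrelated far-away boxes."""
    pred = []
    for (x0, y0, x1, y1) in gt:
        dx, dy = rng.integers(-6, 7, size=2)
        pred.append((x0 + int(dx), y0 + int(dy), x1 + int(dx), y1 + int(dy)))
    for _ in range(extra):
        x, y = rng.integers(300, 400, size=2)
        pred.append((int(x), int(y), int(x) + 20, int(y) + 15))
    return pred


def _gt_image(image_id, labels):
    return labels


class TestCaseLevel:
    def _simple(self):
        gt = {
            "a": [ImprintLabel((0, 0, 10, 10), True, "date", "x")],
            "b": [ImprintLabel((0, 0, 10, 10), False, "marker", "L")],
            "c": [],
        }
        return gt

    def test_perfect_predictions(self):
        gt = self._simple()
        preds = {
            "a": pred_output("a", [("date", (0, 0, 10, 10))]),
            "b": pred_output("b", [("non-phi", (0, 0, 10, 10))]),
            "c": pred_output("c", []),
        }
        report = case_level_eval(gt, preds)
        assert (report.tp, report.fp, report.fn) == (1, 0, 0)
        assert report.precision == 1.0 and report.recall == 1.0

    def test_all_negative_predictor_counts_every_positive_as_fn(self):
        n_pos, n_neg = 85, 15
        gt, preds = {}, {}
        for i in range(n_pos + n_neg):
            k = f"im{i}"
            phi = i < n_pos
            gt[k] = ([ImprintLabel((0, 0, 5, 5), True, "email", "x")]
                     if phi else [])
            preds[k] = pred_output(k, [])
        report = case_level_eval(gt, preds)
        assert report.fn == n_pos and report.recall == 0.0
        assert report.precision is None  # no positive predictions at all

    def test_empty_category_scope_reports_absent_metrics(self):
        gt = self._simple()
        preds = {k: pred_output(k, []) for k in gt}
        report = case_level_eval(gt, preds, scope="email")
        assert report.fp == 0 and report.fn == 0
        assert report.precision is None and report.recall is None

    def test_failed_image_predicts_nothing(self):
        gt = self._simple()
        preds = {
            "a": pred_output("a", [("date", (0, 0, 10, 10))], failed=True),
            "b": pred_output("b", []),
            "c": pred_output("c", []),
        }
        report = case_level_eval(gt, preds)
        assert report.fn == 1 and report.tp == 0

    def test_id_mismatch_raises(self):
        gt = self._simple()
        preds = {"a": pred_output("a", []), "b": pred_output("b", [])}
        with pytest.raises(AlignmentError):
            case_level_eval(gt, preds)


class TestInstanceLevel:
    def _oracle_case(self):
        gt = {"a": [
            ImprintLabel((0, 0, 50, 20), True, "date", "d"),
            ImprintLabel((0, 40, 60, 60), True, "identifier", "i"),
            ImprintLabel((0, 80, 30, 95), False, "marker", "L"),
        ]}
        preds = {"a": pred_output("a", [
            ("date", (0, 0, 50, 20)),
            ("identifier", (0, 40, 60, 60)),
            ("non-phi", (0, 80, 30, 95)),
        ])}
        return gt, preds

    def test_oracle_run_is_perfect(self):
        gt, preds = self._oracle_case()
        report = instance_level_eval(gt, preds)
        assert report.precision == 1.0 and report.recall == 1.0
        assert report.tp == 2  # only PHI instances count

    def test_mislabeled_category_moves_between_scopes(self):
        """A date predicted as identifier keeps overall TP but costs the
        date scope one FN and the identifier scope one FP."""
        gt, _ = self._oracle_case()
        preds = {"a": pred_output("a", [
            ("identifier", (0, 0, 50, 20)),       # mislabeled date
            ("identifier", (0, 40, 60, 60)),
        ])}
        overall = instance_level_eval(gt, preds)
        assert (overall.tp, overall.fp, overall.fn) == (2, 0, 0)
        date = instance_level_eval(gt, preds, scope="date")
        assert (date.tp, date.fp, date.fn) == (0, 0, 1)
        ident = instance_level_eval(gt, preds, scope="identifier")
        assert (ident.tp, ident.fp, ident.fn) == (1, 1, 0)

    def test_duplicate_prediction_adds_exactly_one_fp(self):
        gt, preds = self._oracle_case()
        base = instance_level_eval(gt, preds)
        items = preds["a"].items
        dup = pred_output("a", [
            ("date", (0, 0, 50, 20)), ("date", (1, 0, 51, 20)),
            ("identifier", (0, 40, 60, 60)), ("non-phi", (0, 80, 30, 95)),
        ])
        report = instance_level_eval(gt, {"a": dup})
        assert report.tp == base.tp
        assert report.fp == base.fp + 1

    @pytest.mark.parametrize("k", [1, 2])
    def test_deleting_k_phi_predictions_adds_k_fn(self, k):
        gt, preds = self._oracle_case()
        base = instance_level_eval(gt, preds)
        kept = [("date", (0, 0, 50, 20)),
                ("identifier", (0, 40, 60, 60))][k:]
        report = instance_level_eval(gt, {"a": pred_output("a", kept)})
        assert report.fn == base.fn + k
        assert report.tp == base.tp - k

    def test_coordinate_free_predictions_rejected(self):
        gt, _ = self._oracle_case()
        preds = {"a": pred_output("a", [("date", None)], setup=SetupId.setup4)}
        with pytest.raises(InstanceEvalUnavailableError):
            instance_level_eval(gt, preds)

    def test_failed_image_contributes_all_fn(self):
        gt, _ = self._oracle_case()
        preds = {"a": pred_output("a", [], failed=True)}
        report = instance_level_eval(gt, preds)
        assert report.fn == 2 and report.tp == 0

    def test_case_found_whenever_every_instance_found(self, forced_dataset):
        """If every instance is recovered, every case is recovered too."""
        outs = pl.run_batch(forced_dataset["records"], "setup1",
                            pl.oracle_backends())
        inst = instance_level_eval(forced_dataset["gt"], outs)
        case = case_level_eval(forced_dataset["gt"], outs)
        assert inst.recall == 1.0
        assert case.recall == 1.0


class TestAggregation:
    def _report(self, fn=0.0, recall=1.0):
        return EvalReport(level="case", scope="phi", tp=10, fp=0, fn=fn,
                          precision=1.0, recall=recall)

    def test_identical_runs_have_zero_std(self):
        agg = aggregate_runs([self._report()] * 5)
        assert agg.n_runs == 5
        assert all(v == 0.0 for v in agg.std.values())

    def test_fn_mean_over_five_runs(self):
        reports = [self._report(fn=v) for v in (0, 0, 1, 0, 1)]
        agg = aggregate_runs(reports)
        assert agg.fn == pytest.approx(0.4)
        assert agg.std["fn"] == pytest.approx(np.std([0, 0, 1, 0, 1], ddof=1))

    def test_single_run_passes_through_without_std(self):
        report = self._report()
        agg = aggregate_runs([report])
        assert agg is report and agg.std is None

    def test_mixed_scopes_raise(self):
        other = EvalReport(level="case", scope="date", tp=1, fp=0, fn=0,
                           precision=1.0, recall=1.0)
        with pytest.raises(AggregationError):
            aggregate_runs([self._report(), other])

    def test_dataframe_shape(self):
        agg = aggregate_runs([self._report(fn=v) for v in (0, 1, 2)])
        frame = ev.reports_to_dataframe([agg])
        assert set(frame.columns) >= {"level", "scope", "precision", "recall",
                                      "fp", "fn", "recall_std"}
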