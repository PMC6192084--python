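import math

import numpy as np
import pytest

from crowdcbr.errors import DomainError
from crowdcbr.evaluation import (
    ConfusionMatrix,
    ROCCurve,
    auc,
    basic_metrics,
    confusion,
    macro_average,
    metrics_report,
    ppv_npv,
    roc_from_point,
    roc_from_scores,
    round_half_up,
    weighted_average,
)
from crowdcbr.io_survey import ABNORMAL, NORMAL


class TestConfusion:
    def test_perfect_predictions(self):
        truth = [ABNORMAL] * 2 + [NORMAL] * 8
        cm = confusion(truth, truth)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 8, 0, 0)

    def test_all_majority(self):
        truth = [ABNORMAL] * 3 + [NORMAL] * 7
        cm = confusion(truth, [NORMAL] * 10)
        assert cm.tp == 0 and cm.fn == 3 and cm.tn == 7

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pairwise_counting(self, seed):
        rng = np.random.default_rng(seed)
        truth = [ABNORMAL if x else NORMAL for x in rng.integers(0, 2, 50)]
        pred = [ABNORMAL if x else NORMAL for x in rng.integers(0, 2, 50)]
        cm = confusion(truth, pred)
        assert cm.tp == sum(t == ABNORMAL and p == ABNORMAL for t, p in zip(truth, pred))
        assert cm.fn == sum(t == ABNORMAL and p == NORMAL for t, p in zip(truth, pred))
        assert cm.fp == sum(t == NORMAL and p == ABNORMAL for t, p in zip(truth, pred))
        assert cm.total == 50

    def test_unknown_label(self):
        with pytest.raises(DomainError):
            confusion(["weird"], [NORMAL])


class TestBasicMetrics:
    def test_direct_arithmetic(self):
        m = basic_metrics(ConfusionMatrix(tp=9, fn=1, fp=2, tn=8))
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["tp_rate"] == pytest.approx(0.9)
        assert m["fp_rate"] == pytest.approx(0.2)
        assert m["precision"] == pytest.approx(9 / 11)
        assert m["recall"] == m["tp_rate"]

    def test_zero_denominator_is_nan_sentinel(self):
        m = basic_metrics(ConfusionMatrix(tp=3, fn=1, fp=0, tn=0))
        assert math.isnan(m["fp_rate"])

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matrices_match_re_derivation(self, seed):
        rng = np.random.default_rng(seed)
        tp, fn, fp, tn = (int(x) for x in rng.integers(1, 50, 4))
        m = basic_metrics(ConfusionMatrix(tp, fn, fp, tn))
        assert m["accuracy"] == pytest.approx((tp + tn) / (tp + fn + fp + tn))
        assert m["precision"] == pytest.approx(tp / (tp + fp))


class TestAverages:
    def test_macro_published_rows(self):
        assert macro_average([0.984, 0.227], ndigits=3) == pytest.approx(0.606)
        assert macro_average([0.940, 0.600], ndigits=3) == pytest.approx(0.770)

    def test_macro_singleton(self):
        assert macro_average([0.42]) == 0.42

    def test_round_half_up_convention(self):
        assert round_half_up(0.6055, 3) == 0.606
        assert round_half_up(0.3505, 3) == 0.351

    def test_weighted_equals_macro_for_equal_counts(self):
        vals = [0.3, 0.7]
        assert weighted_average(vals, [5, 5]) == pytest.approx(macro_average(vals))

    def test_weighted_prevalence(self):
        assert weighted_average([1.0, 0.0], [9, 1]) == pytest.approx(0.9)

    @pytest.mark.parametrize(
        "task", ["stress", "depression"]
    )
    def test_published_macro_rows_reproduced(self, task):
        """Every classifier block: the unweighted mean of the printed
        per-class rates reproduces the printed macro row within 0.0005
        (9 classifiers x 4 metrics per task)."""
        from crowdcbr.datasets import load_performance_table

        frame = load_performance_table(task).set_index(["classifier", "row"])
        classifiers = frame.index.get_level_values(0).unique()
        assert len(classifiers) == 9
        for clf in classifiers:
            for metric in ("tp_rate", "fp_rate", "precision", "recall"):
                per_class = [
                    frame.loc[(clf, "normal"), metric],
                    frame.loc[(clf, "serious"), metric],
                ]
                printed = frame.loc[(clf, "overall_norm"), metric]
                # half-ulp rounding cases sit exactly at the boundary
                assert abs(macro_average(per_class) - printed) <= 0.0005 + 1e-12, (
                    task, clf, metric,
                )

    def test_micro_identity(self):
        """Overall accuracy equals the prevalence-weighted per-class recalls."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            tp, fn, fp, tn = (int(x) for x in rng.integers(1, 80, 4))
            cm = ConfusionMatrix(tp, fn, fp, tn)
            recalls = [
                basic_metrics(cm)["recall"],
                basic_metrics(cm.swapped())["recall"],
            ]
            counts = [tp + fn, fp + tn]
            assert weighted_average(recalls, counts) == pytest.approx(
                basic_metrics(cm)["accuracy"]
            )


class TestPredictiveValues:
    def test_perfect(self):
        out = ppv_npv(ConfusionMatrix(tp=10, fn=0, fp=0, tn=10))
        assert out["textbook"] == {"ppv": 1.0, "npv": 1.0}
        assert out["per_class_recall"] == {"ppv": 1.0, "npv": 1.0}

    def test_textbook_half(self):
        out = ppv_npv(ConfusionMatrix(tp=1, fn=0, fp=1, tn=1))
        assert out["textbook"]["ppv"] == pytest.approx(0.5)

    def test_conventions_differ_under_imbalance(self):
        # many majority false positives: recall-style PPV stays high,
        # textbook PPV collapses
        out = ppv_npv(ConfusionMatrix(tp=9, fn=1, fp=30, tn=60))
        assert out["per_class_recall"]["ppv"] == pytest.approx(0.9)
        assert out["textbook"]["ppv"] == pytest.approx(9 / 39)


class TestROC:
    def test_perfect_classifier_point(self):
        curve = roc_from_point(ConfusionMatrix(tp=5, fn=0, fp=0, tn=5))
        assert curve.points == [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
        assert auc(curve) == pytest.approx(1.0)

    def test_chance_classifier_on_diagonal(self):
        curve = roc_from_point(ConfusionMatrix(tp=3, fn=3, fp=5, tn=5))
        fpr, tpr = curve.points[1]
        assert fpr == pytest.approx(tpr)
        assert auc(curve) == pytest.approx(0.5)

    def test_single_point_auc_formula(self):
        cm = ConfusionMatrix(tp=9, fn=1, fp=2, tn=8)
        m = basic_metrics(cm)
        assert auc(roc_from_point(cm)) == pytest.approx(
            (1 + m["tp_rate"] - m["fp_rate"]) / 2
        )

    def test_auc_increases_with_separation(self):
        aucs = [
            auc(roc_from_point(ConfusionMatrix(tp=tp, fn=10 - tp, fp=2, tn=8)))
            for tp in range(0, 11)
        ]
        assert aucs == sorted(aucs)

    def test_perfect_ranking_scores(self):
        truth = [ABNORMAL] * 3 + [NORMAL] * 7
        scores = [0.9, 0.8, 0.7] + [0.1 * i for i in range(7)]
        assert auc(roc_from_scores(truth, scores)) == pytest.approx(1.0)

    def test_reversed_ranking_scores(self):
        truth = [ABNORMAL] * 3 + [NORMAL] * 7
        scores = [0.0, 0.1, 0.2] + [0.5 + 0.05 * i for i in range(7)]
        assert auc(roc_from_scores(truth, scores)) == pytest.approx(0.0)

    def test_constant_scores_degenerate_diagonal(self):
        truth = [ABNORMAL, NORMAL, NORMAL]
        curve = roc_from_scores(truth, [0.5, 0.5, 0.5])
        assert curve.points == [(0.0, 0.0), (1.0, 1.0)]
        assert auc(curve) == pytest.approx(0.5)

    def test_hand_enumerated_five_points(self):
        truth = [ABNORMAL, NORMAL, ABNORMAL, NORMAL, NORMAL]
        scores = [0.9, 0.8, 0.6, 0.6, 0.1]
        curve = roc_from_scores(truth, scores)
        # sweep: 0.9 -> (0,1/2); 0.8 -> (1/3,1/2); 0.6 (tie of one pos one neg)
        # -> (2/3,1); 0.1 -> (1,1)
        assert curve.points == [
            (0.0, 0.0), (0.0, 0.5), (1 / 3, 0.5), (2 / 3, 1.0), (1.0, 1.0)
        ]

    def test_matches_sklearn_oracle(self):
        """Cross-check the sweep + trapezoid against an independent library."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(10):
            y = rng.integers(0, 2, 60)
            if y.sum() in (0, 60):
                continue
            scores = rng.random(60) + 0.5 * y
            truth = [ABNORMAL if t else NORMAL for t in y]
            ours = auc(roc_from_scores(truth, scores))
            assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-9)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 4000)
        scores = rng.random(4000)
        truth = [ABNORMAL if t else NORMAL for t in y]
        assert auc(roc_from_scores(truth, scores)) == pytest.approx(0.5, abs=0.05)

    def test_invalid_curves_rejected(self):
        with pytest.raises(DomainError):
            ROCCurve([(0.0, 0.0), (0.5, 0.4)])
        with pytest.raises(DomainError):
            ROCCurve([(0.0, 0.0), (0.6, 0.2), (0.3, 0.9), (1.0, 1.0)])


class TestReport:
    def test_report_consistency(self):
        truth = [ABNORMAL] * 4 + [NORMAL] * 36
        pred = [ABNORMAL] * 3 + [NORMAL] + [ABNORMAL] * 2 + [NORMAL] * 34
        report = metrics_report(truth, pred)
        cm = report.confusion_matrix
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 1, 2, 34)
        assert report.overall_accuracy == pytest.approx(100 * 37 / 40, abs=1e-4)
        assert report.per_class[ABNORMAL]["tp_rate"] == pytest.approx(0.75)
        assert report.per_class[NORMAL]["tp_rate"] == pytest.approx(
            round(34 / 36, 3), abs=1e-3
        )
        assert report.overall_norm["tp_rate"] == pytest.approx(
            round((0.75 + 34 / 36) / 2, 3), abs=1e-3
        )
        # recall-convention predictive values are the per-class TP rates
        pv = report.predictive_values["per_class_recall"]
        assert pv["ppv"] == pytest.approx(0.75)
        assert pv["npv"] == pytest.approx(34 / 36)

    def test_json_round_trip(self, tmp_path):
        import json

        truth = [ABNORMAL] * 2 + [NORMAL] * 8
        report = metrics_report(truth, truth)
        path = tmp_path / "metrics.json"
        report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["overall_accuracy"] == 100.0
        assert payload["auc_single_point"] == 1.0
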