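"""Metric formulas against independent oracles (hand arithmetic, sklearn,
Mann-Whitney rank statistics)."""

import math

import numpy as np
import pytest
from scipy.stats import rankdata

from histotex import (
    ConfusionCounts,
    compute_metrics,
    comparison_report,
    confusion_matrix,
    macro_average,
    roc_auc,
)


def counts_to_labels(c: ConfusionCounts):
    """Reconstruct binary label/prediction vectors realizing the counts."""
    y_true = ["pos"] * (c.tp + c.fn) + ["neg"] * (c.fp + c.tn)
    y_pred = ["pos"] * c.tp + ["neg"] * c.fn + ["pos"] * c.fp + ["neg"] * c.tn
    return np.array(y_true), np.array(y_pred)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = ["a", "b", "c", "a"]
        mat, per = confusion_matrix(y, y, classes=["a", "b", "c"])
        assert (mat.to_numpy() == np.diag([2, 1, 1])).all()
        for c in per.values():
            assert c.fp == 0 and c.fn == 0

    def test_entries_sum_to_n(self, rng):
        classes = list("abcd")
        y_true = rng.choice(classes, 100)
        y_pred = rng.choice(classes, 100)
        mat, per = confusion_matrix(y_true, y_pred, classes)
        assert mat.to_numpy().sum() == 100
        for c in per.values():
            assert c.n == 100

    def test_hand_enumerated_three_sample_case(self):
        mat, per = confusion_matrix(["a", "a", "b"], ["a", "b", "b"], classes=["a", "b"])
        a = per["a"]
        assert (a.tp, a.fn, a.fp, a.tn) == (1, 1, 0, 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in classes"):
            confusion_matrix(["a"], ["z"], classes=["a", "b"])


class TestMetricFormulas:
    def test_perfect_case_all_ones(self):
        rep = compute_metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
        assert rep.precision == rep.f1 == rep.mcc == 1.0

    def test_balanced_coin_case(self):
        rep = compute_metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert rep.accuracy == 0.5
        assert rep.precision == 0.5
        assert rep.f1 == 0.5
        assert rep.mcc == 0.0

    def test_degenerate_zero_positives(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert rep.sensitivity == 0.0
        assert rep.precision == 0.0  # 0/0 policy
        assert rep.mcc == 0.0
        assert rep.warnings  # structured notes attached

    def test_battery_of_random_quadruples_matches_hand_substitution(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 200, size=4))
            rep = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            n = tp + fp + tn + fn
            assert abs(rep.accuracy - (tp + tn) / n) < 1e-12
            assert abs(rep.sensitivity - tp / (tp + fn)) < 1e-12
            assert abs(rep.specificity - tn / (tn + fp)) < 1e-12
            assert abs(rep.precision - tp / (tp + fp)) < 1e-12
            assert abs(rep.f1 - 2 * tp / (2 * tp + fp + fn)) < 1e-12
            mcc = (tp * tn - fp * fn) / math.sqrt(
                (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            )
            assert abs(rep.mcc - mcc) < 1e-12

    def test_against_sklearn_on_reconstructed_labels(self):
        from sklearn.metrics import f1_score, matthews_corrcoef, precision_score, recall_score

        rng = np.random.default_rng(9)
        for _ in range(20):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 50, size=4)))
            y_true, y_pred = counts_to_labels(c)
            rep = compute_metrics(c)
            assert rep.sensitivity == pytest.approx(recall_score(y_true, y_pred, pos_label="pos"))
            assert rep.precision == pytest.approx(precision_score(y_true, y_pred, pos_label="pos"))
            assert rep.f1 == pytest.approx(f1_score(y_true, y_pred, pos_label="pos"))
            assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestMacroAverage:
    def test_identical_reports_average_to_themselves(self):
        rep = compute_metrics(ConfusionCounts(8, 2, 7, 3))
        macro = macro_average([rep] * 4)
        assert macro.f1 == rep.f1 and macro.mcc == rep.mcc
        assert macro.averaging == "macro"

    def test_arithmetic_mean_of_mixed_reports(self):
        perfect = compute_metrics(ConfusionCounts(1, 0, 1, 0))
        coin = compute_metrics(ConfusionCounts(1, 1, 1, 1))
        macro = macro_average([perfect, perfect, coin, coin])
        assert macro.precision == pytest.approx(0.75)
        assert macro.accuracy == pytest.approx(0.75)

    def test_overall_accuracy_is_trace_over_n(self, rng):
        classes = list("abcd")
        y_true = rng.choice(classes, 60)
        y_pred = rng.choice(classes, 60)
        mat, per = confusion_matrix(y_true, y_pred, classes)
        macro = macro_average([compute_metrics(per[c]) for c in classes], confusion=mat)
        assert macro.overall_accuracy == pytest.approx(np.trace(mat.to_numpy()) / 60)


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        y = ["pos"] * 5 + ["neg"] * 5
        s = [0.9, 0.8, 0.85, 0.95, 0.7, 0.3, 0.2, 0.1, 0.15, 0.25]
        assert roc_auc(y, s, "pos").auc == 1.0

    def test_random_scores_give_half(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["pos", "neg"], 10_000)
        s = rng.standard_normal(10_000)
        assert roc_auc(y, s, "pos").auc == pytest.approx(0.5, abs=0.02)

    def test_antisymmetry(self, rng):
        y = rng.choice(["pos", "neg"], 200)
        s = rng.standard_normal(200)
        assert roc_auc(y, s, "pos").auc + roc_auc(y, -s, "pos").auc == pytest.approx(1.0)

    def test_equals_mann_whitney_with_ties(self, rng):
        """Trapezoidal AUC must equal the rank-based Mann-Whitney statistic,
        including under heavy score ties."""
        for trial in range(10):
            y = rng.choice(["pos", "neg"], 120)
            s = rng.integers(0, 8, 120).astype(float)  # many ties
            pos = y == "pos"
            ranks = rankdata(s)
            u = ranks[pos].sum() - pos.sum() * (pos.sum() + 1) / 2
            mw = u / (pos.sum() * (~pos).sum())
            assert abs(roc_auc(y, s, "pos").auc - mw) < 1e-12

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.choice(["pos", "neg"], 300)
        s = rng.standard_normal(300)
        assert roc_auc(y, s, "pos").auc == pytest.approx(
            roc_auc_score(y == "pos", s), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(["pos", "pos"], [0.1, 0.2], "pos")

    def test_curve_frame_columns(self, rng):
        y = rng.choice(["pos", "neg"], 50)
        curve = roc_auc(y, rng.standard_normal(50), "pos")
        frame = curve.to_frame()
        assert list(frame.columns) == ["fpr", "tpr", "threshold"]
        assert frame["fpr"].iloc[0] == 0.0 and frame["fpr"].iloc[-1] == 1.0


class TestComparisonReport:
    def _grid(self, missing=False):
        grid = {}
        for fs in ("original", "glcm", "glrm", "glcm+glrm", "full"):
            for clf in ("lda", "qda", "svm", "nb", "knn", "rf"):
                if missing and (fs, clf) == ("full", "rf"):
                    continue
                grid[("tiny_cnn", fs, clf)] = {"overall_accuracy": 0.9}
        return grid

    def test_complete_grid_has_all_cells_in_percent(self, tmp_path):
        table = comparison_report(self._grid(), out_dir=tmp_path)
        assert table.shape == (6, 5)
        assert table.notna().all().all()
        assert ((table >= 0) & (table <= 100)).all().all()
        assert (tmp_path / "comparison_grid.csv").exists()
        assert (tmp_path / "comparison_grid.json").exists()

    def test_missing_cells_reported_not_dropped(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            table = comparison_report(self._grid(missing=True), out_dir=tmp_path)
        assert table.isna().sum().sum() == 1
        assert any("missing" in r.message for r in caplog.records)
        import json

        payload = json.loads((tmp_path / "comparison_grid.json").read_text())
        assert payload["missing_cells"] == ["tiny_cnn/full/rf"]
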