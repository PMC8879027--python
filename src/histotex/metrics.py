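"""Classification performance metrics, ROC/AUC and comparison reports.

The metric suite is computed from one-vs-rest confusion counts per class:

    accuracy    = (TP + TN) / (TN + FP + FN + TP)
    sensitivity = TP / (TP + FN)                      (recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 TP / (2 TP + FP + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate 0/0 ratios (e.g. precision with no positive predictions, the MCC
denominator vanishing) are defined as 0 and flagged with a structured
warning rather than propagating NaNs.  Multiclass results are reported per
class and macro-averaged (unweighted mean over classes), alongside the
overall multiclass accuracy trace(confusion)/n.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocCurve",
    "confusion_matrix",
    "compute_metrics",
    "macro_average",
    "roc_auc",
    "comparison_report",
]

logger = logging.getLogger(__name__)

#: Canonical feature-set column order of the comparison grid.
FEATURE_SETS = ("original", "glcm", "glrm", "glcm+glrm", "full")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError(f"confusion counts must be non-negative: {self}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """The six-metric suite for one class (or a macro average)."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    auc: float | None = None
    averaging: str = "per_class"
    overall_accuracy: float | None = None
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.overall_accuracy is not None:
            d["overall_accuracy"] = self.overall_accuracy
        return d


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, classes: Sequence
) -> tuple[pd.DataFrame, dict[object, ConfusionCounts]]:
    """K x K confusion matrix (rows = true, cols = predicted) plus per-class
    one-vs-rest TP/FP/TN/FN derived from it."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"label vectors differ in length: {len(y_true)} vs {len(y_pred)}")
    class_list = list(classes)
    unknown = (set(y_true) | set(y_pred)) - set(class_list)
    if unknown:
        raise ValueError(f"labels {sorted(map(str, unknown))} not in classes {class_list}")
    idx = {c: i for i, c in enumerate(class_list)}
    mat = np.zeros((len(class_list), len(class_list)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    df = pd.DataFrame(mat, index=class_list, columns=class_list)
    n = int(mat.sum())
    per_class = {}
    for c in class_list:
        i = idx[c]
        tp = int(mat[i, i])
        fp = int(mat[:, i].sum() - tp)
        fn = int(mat[i, :].sum() - tp)
        per_class[c] = ConfusionCounts(tp=tp, fp=fp, tn=n - tp - fp - fn, fn=fn)
    return df, per_class


def _ratio(num: float, den: float, name: str, warnings_out: list[str]) -> float:
    if den == 0:
        warnings_out.append(f"{name} undefined (0/0); reported as 0")
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate the six-metric suite for one positive class."""
    if counts.n == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    w: list[str] = []
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = (tp + tn) / counts.n
    sensitivity = _ratio(tp, tp + fn, "sensitivity", w)
    specificity = _ratio(tn, tn + fp, "specificity", w)
    precision = _ratio(tp, tp + fp, "precision", w)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", w)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        w.append("mcc denominator 0; reported as 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    for msg in w:
        logger.warning("metric note: %s", msg)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        mcc=mcc,
        warnings=w,
    )


def macro_average(
    per_class_reports: Sequence[MetricsReport],
    confusion: pd.DataFrame | None = None,
) -> MetricsReport:
    """Unweighted mean of each metric across classes; when the multiclass
    confusion matrix is supplied, the overall accuracy trace/n is attached."""
    if not per_class_reports:
        raise ValueError("need at least one per-class report")

    def mean(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in per_class_reports]))

    aucs = [r.auc for r in per_class_reports if r.auc is not None]
    overall = None
    if confusion is not None:
        mat = confusion.to_numpy()
        overall = float(np.trace(mat) / mat.sum())
    return MetricsReport(
        accuracy=mean("accuracy"),
        sensitivity=mean("sensitivity"),
        specificity=mean("specificity"),
        precision=mean("precision"),
        f1=mean("f1"),
        mcc=mean("mcc"),
        auc=float(np.mean(aucs)) if aucs else None,
        averaging="macro",
        overall_accuracy=overall,
        warnings=[w for r in per_class_reports for w in r.warnings],
    )


@dataclass
class RocCurve:
    """ROC points from a threshold sweep plus trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


def roc_auc(y_true: Sequence, scores: Sequence[float], positive_class) -> RocCurve:
    """One-vs-rest ROC by sweeping thresholds over the unique scores.

    AUC is the trapezoidal area under the resulting curve, which with the
    midpoint handling of tied scores equals the normalized Mann-Whitney U
    statistic of the positive- vs negative-class score distributions.
    """
    y = np.asarray(y_true) == positive_class
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("y_true and scores must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative samples")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # evaluate at the last index of each tied score block
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], dtype=int)
    cut = np.concatenate([distinct, [len(s_sorted) - 1]])
    tps = np.cumsum(y_sorted)[cut]
    fps = (cut + 1) - tps
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def comparison_report(
    grid_results: Mapping[tuple[str, str, str], Mapping[str, float]],
    out_dir: str | Path | None = None,
    classifiers: Sequence[str] | None = None,
    feature_sets: Sequence[str] = FEATURE_SETS,
) -> pd.DataFrame:
    """Tabulate the (backbone x feature-set x classifier) accuracy grid.

    ``grid_results`` maps ``(backbone, feature_set, classifier)`` to a
    metrics mapping containing at least ``overall_accuracy`` (fraction).
    Rows are classifiers; columns are (backbone, feature-set) pairs holding
    accuracy in percent.  Missing cells are reported (NaN + logged warning),
    never silently dropped.  When ``out_dir`` is given the table is written
    as CSV with a JSON twin.
    """
    backbones = sorted({b for b, _, _ in grid_results})
    if classifiers is None:
        classifiers = sorted({c for _, _, c in grid_results})
    columns = pd.MultiIndex.from_product(
        [backbones, list(feature_sets)], names=["backbone", "feature_set"]
    )
    table = pd.DataFrame(np.nan, index=pd.Index(classifiers, name="classifier"), columns=columns)
    for (backbone, feature_set, clf), metrics in grid_results.items():
        table.loc[clf, (backbone, feature_set)] = 100.0 * float(metrics["overall_accuracy"])
    missing = [
        (str(c), str(b), str(fs))
        for (b, fs) in table.columns
        for c in table.index
        if pd.isna(table.loc[c, (b, fs)])
    ]
    if missing:
        logger.warning("comparison grid has %d missing cells: %s", len(missing), missing[:10])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "comparison_grid.csv")
        payload = {
            "accuracy_percent": {
                f"{b}/{fs}/{c}": (None if pd.isna(v) else round(float(v), 4))
                for (b, fs), col in table.items()
                for c, v in col.items()
            },
            "missing_cells": [f"{b}/{fs}/{c}" for c, b, fs in missing],
        }
        with open(out_dir / "comparison_grid.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    return table
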