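"""Six-classifier bank and leakage-safe cross-validation.

The bank mirrors the comparison grid of the study: linear and quadratic
discriminant analysis (LDA/QDA), a quadratic-kernel support vector machine
(Q-SVM, one-vs-one), Gaussian naive Bayes, k-nearest neighbors (k=5) and a
100-tree random forest.  Scale-sensitive kinds (svm, knn) get fold-local
feature standardization; the rest see raw features.  Evaluation uses
stratified, group-aware k-fold cross-validation so augmented copies can
never land in a different fold than their parent image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "ClassifierHandle",
    "CVProtocol",
    "CVResult",
    "train_classifier",
    "predict",
    "cross_validate",
]

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("lda", "qda", "svm", "nb", "knn", "rf")

_DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "lda": {"ridge_shrinkage": 1e-3},
    "qda": {"reg_param": 0.0, "ridge_shrinkage": 1e-3},
    "svm": {"kernel": "poly", "degree": 2, "C": 1.0, "coef0": 1.0, "gamma": "scale"},
    "nb": {},
    "knn": {"k": 5, "metric": "euclidean"},
    "rf": {"n_trees": 100, "max_features": "sqrt"},
}

#: Kinds whose estimators get fold-local standardization.
_SCALED_KINDS = {"svm", "knn"}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier kind plus its (validated) hyperparameters."""

    kind: str
    hyperparams: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}")
        unknown = set(self.hyperparams) - set(_DEFAULT_HYPERPARAMS[self.kind])
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind!r}: {sorted(unknown)}")

    def resolved(self) -> dict:
        hp = dict(_DEFAULT_HYPERPARAMS[self.kind])
        hp.update(self.hyperparams)
        return hp


@dataclass
class ClassifierHandle:
    """A fitted estimator plus the spec and training-column contract."""

    spec: ClassifierSpec
    estimator: object
    n_features: int
    classes: np.ndarray


@dataclass(frozen=True)
class CVProtocol:
    """Stratified group-aware k-fold settings."""

    k: int = 5
    seed: int = 0


@dataclass
class CVResult:
    """Out-of-fold predictions plus per-fold and pooled confusion matrices."""

    y_true: pd.Series
    y_pred: pd.Series
    scores: pd.DataFrame  # per-class scores aligned with y_true
    fold: pd.Series
    confusion: pd.DataFrame  # pooled, rows = true class, cols = predicted
    fold_confusions: list[pd.DataFrame]

    @property
    def accuracy(self) -> float:
        return float((self.y_true == self.y_pred).mean())


def _build_estimator(spec: ClassifierSpec, ridge: bool = False):
    hp = spec.resolved()
    if spec.kind == "lda":
        if ridge:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=hp["ridge_shrinkage"])
        return LinearDiscriminantAnalysis(solver="svd")
    if spec.kind == "qda":
        if ridge:
            # eigen solver + shrinkage handles n_samples_per_class < n_features;
            # tiny tol keeps near-constant within-class features from failing
            # the rank check after shrinkage
            return QuadraticDiscriminantAnalysis(
                solver="eigen", shrinkage=hp["ridge_shrinkage"], tol=1e-12
            )
        return QuadraticDiscriminantAnalysis(reg_param=hp["reg_param"])
    if spec.kind == "svm":
        svc = SVC(
            kernel=hp["kernel"],
            degree=hp["degree"],
            C=hp["C"],
            coef0=hp["coef0"],
            gamma=hp["gamma"],
            decision_function_shape="ovr",
        )
        return Pipeline([("scale", StandardScaler()), ("svc", svc)])
    if spec.kind == "nb":
        return GaussianNB()
    if spec.kind == "knn":
        knn = KNeighborsClassifier(n_neighbors=hp["k"], metric=hp["metric"])
        return Pipeline([("scale", StandardScaler()), ("knn", knn)])
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=hp["n_trees"],
            max_features=hp["max_features"],
            random_state=spec.seed,
        )
    raise ValueError(spec.kind)  # pragma: no cover


def train_classifier(spec: ClassifierSpec, X, y) -> ClassifierHandle:
    """Fit one classifier; LDA/QDA fall back to a ridge-regularized fit (with
    a logged warning) when class covariances are singular/collinear."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError(f"X must be 2-D with one row per label, got {X.shape} vs {len(y)}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes to train, got {classes.tolist()}")

    est = _build_estimator(spec)
    degenerate: list = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            est.fit(X, y)
        degenerate = [
            w for w in caught
            if "collinear" in str(w.message).lower() or "singular" in str(w.message).lower()
        ]
    except np.linalg.LinAlgError as exc:
        if spec.kind not in ("lda", "qda"):
            raise
        degenerate = [exc]
    if degenerate and spec.kind in ("lda", "qda"):
        logger.warning(
            "%s fit hit singular/collinear covariance; refitting with ridge regularization",
            spec.kind,
        )
        est = _build_estimator(spec, ridge=True)
        est.fit(X, y)
    return ClassifierHandle(spec=spec, estimator=est, n_features=X.shape[1], classes=classes)


def predict(handle: ClassifierHandle, X) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted labels plus per-class scores (probabilities where the kind
    is probabilistic, one-vs-rest decision values for the SVM)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != handle.n_features:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"expected {handle.n_features}"
        )
    est = handle.estimator
    labels = est.predict(X)
    if hasattr(est, "predict_proba"):
        scores = est.predict_proba(X)
    else:
        scores = est.decision_function(X)
        if scores.ndim == 1:  # binary: expand to per-class columns
            scores = np.column_stack([-scores, scores])
    return labels, pd.DataFrame(scores, columns=list(handle.classes))


def _confusion_df(y_true, y_pred, classes) -> pd.DataFrame:
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    return pd.DataFrame(mat, index=list(classes), columns=list(classes))


def cross_validate(
    spec: ClassifierSpec,
    X,
    y,
    protocol: CVProtocol = CVProtocol(),
    groups: Sequence | None = None,
) -> CVResult:
    """Stratified group-aware k-fold CV: every sample is predicted exactly
    once by a model that saw neither it nor any sample sharing its group
    (e.g. augmented copies of the same parent image)."""
    if isinstance(X, pd.DataFrame):
        index = X.index
        X_arr = X.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X, dtype=float)
        index = pd.RangeIndex(len(X_arr))
    y_arr = np.asarray(y)
    classes = np.unique(y_arr)
    counts = pd.Series(y_arr).value_counts()
    if counts.min() < protocol.k:
        raise ValueError(
            f"class {counts.idxmin()!r} has only {counts.min()} samples, fewer than "
            f"k={protocol.k} folds; use a smaller k"
        )
    if groups is None:
        groups = np.asarray(index)
    groups = np.asarray(groups)

    splitter = StratifiedGroupKFold(n_splits=protocol.k, shuffle=True, random_state=protocol.seed)
    y_pred = pd.Series(index=index, dtype=object)
    fold_ids = pd.Series(index=index, dtype=int)
    scores = pd.DataFrame(np.nan, index=index, columns=list(classes))
    fold_confusions = []
    for fold_no, (tr, te) in enumerate(splitter.split(X_arr, y_arr, groups=groups)):
        handle = train_classifier(spec, X_arr[tr], y_arr[tr])
        labels, sc = predict(handle, X_arr[te])
        y_pred.iloc[te] = labels
        fold_ids.iloc[te] = fold_no
        scores.iloc[te, [scores.columns.get_loc(c) for c in sc.columns]] = sc.to_numpy()
        fold_confusions.append(_confusion_df(y_arr[te], labels, classes))
    pooled = sum(fold_confusions[1:], fold_confusions[0].copy())
    return CVResult(
        y_true=pd.Series(y_arr, index=index, name="label"),
        y_pred=y_pred.rename("predicted"),
        scores=scores,
        fold=fold_ids.rename("fold"),
        confusion=pooled,
        fold_confusions=fold_confusions,
    )
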