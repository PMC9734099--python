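"""Marker and profile classification.

Three classifiers mirror the marker-evaluation stage of the pipeline:

* single-protein linear discriminant analysis (1-D Gaussian LDA with pooled
  variance and class-frequency priors) scored by leave-one-out
  cross-validation — the per-marker accuracy column of the differential
  tables;
* PCA-LDA: per-fold standardization, PCA retaining a fixed fraction of the
  variance, then LDA on the scores;
* PLS-DA: partial least squares regression on one-hot class indicators with
  the predicted class taken as the argmax of the fitted indicators, and the
  number of latent variables chosen by the oneSE rule (smallest model whose
  mean cross-validated accuracy is within one standard error of the best).

``PCALDAClassifier`` and ``PLSDAClassifier`` are scikit-learn compatible
estimators and work with sklearn model selection; the ``*_cv`` functions are
thin wrappers running the study's cross-validation schemes (leave-one-out or
stratified repeated k-fold, k=10, times=3). Missing quantification values
enter every model as 0 (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, RepeatedStratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array


@dataclass
class CVScheme:
    """Cross-validation scheme: leave-one-out or repeated stratified k-fold."""

    kind: str = "loocv"  # {"loocv", "repeated_kfold"}
    k: int = 10
    times: int = 3
    seed: int = 0
    stratified: bool = True

    def splitter(self, y: np.ndarray):
        if self.kind == "loocv":
            return LeaveOneOut()
        if self.kind == "repeated_kfold":
            if not self.stratified:
                from sklearn.model_selection import RepeatedKFold

                return RepeatedKFold(
                    n_splits=self.k, n_repeats=self.times, random_state=self.seed
                )
            _, counts = np.unique(y, return_counts=True)
            if self.k > counts.min():
                raise ValueError(
                    f"k={self.k} exceeds smallest class size {counts.min()}"
                )
            return RepeatedStratifiedKFold(
                n_splits=self.k, n_repeats=self.times, random_state=self.seed
            )
        raise ValueError(f"unknown CV kind {self.kind!r}")


@dataclass
class ClassificationReport:
    """Cross-validated accuracy summary for one model and contrast."""

    model: str
    classes: list
    accuracy: float  # percent
    fold_accuracies: list[float] = field(default_factory=list)
    n_latent: int | None = None
    confusion: pd.DataFrame | None = None
    third_group_assignment: dict | None = None

    @property
    def accuracy_se(self) -> float:
        a = np.asarray(self.fold_accuracies)
        if a.size < 2:
            return 0.0
        return float(a.std(ddof=1) / np.sqrt(a.size))


def _zero_fill(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.nan_to_num(X, nan=0.0)


class PCALDAClassifier(ClassifierMixin, BaseEstimator):
    """Standardize, project onto principal components, classify by LDA.

    Parameters
    ----------
    variance_kept : fraction of training variance the retained components must
        cover (default 0.95); an int requests a fixed component count.
    scale : unit-variance scale features before PCA (centering always on).
    priors : LDA class priors; None = class frequencies of the training data.
    """

    def __init__(self, variance_kept: float = 0.95, scale: bool = True, priors=None):
        self.variance_kept = variance_kept
        self.scale = scale
        self.priors = priors

    def fit(self, X, y):
        X, y = check_X_y(_zero_fill(X), y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        # zero-variance features carry no information; drop them for this fit
        self.feature_mask_ = X.std(axis=0) > 0
        Xs = X[:, self.feature_mask_]
        self.scaler_ = StandardScaler(with_std=self.scale).fit(Xs)
        Z = self.scaler_.transform(Xs)
        n_comp = self.variance_kept
        max_comp = min(Z.shape[0] - 1, Z.shape[1])
        if isinstance(n_comp, int):
            n_comp = min(n_comp, max_comp)
        self.pca_ = PCA(n_components=n_comp, svd_solver="full").fit(Z)
        scores = self.pca_.transform(Z)
        self.lda_ = LinearDiscriminantAnalysis(priors=self.priors).fit(scores, y)
        return self

    def _project(self, X) -> np.ndarray:
        X = check_array(_zero_fill(X))
        return self.pca_.transform(self.scaler_.transform(X[:, self.feature_mask_]))

    def predict(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict(self._project(X))

    def predict_proba(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict_proba(self._project(X))


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA: PLS regression on one-hot class indicators, argmax prediction.

    Ties in the predicted indicators resolve to the alphabetically lowest
    class label. ``n_components`` is the number of latent variables.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X, y = check_X_y(_zero_fill(X), y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.feature_mask_ = X.std(axis=0) > 0
        Xs = X[:, self.feature_mask_]
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        n_comp = min(self.n_components, Xs.shape[0] - 1, Xs.shape[1])
        self.n_components_ = n_comp
        self.pls_ = PLSRegression(n_components=n_comp, scale=self.scale).fit(Xs, Y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pls_")
        X = check_array(_zero_fill(X))
        return self.pls_.predict(X[:, self.feature_mask_])

    def predict(self, X):
        scores = self.decision_function(X)
        # np.argmax takes the first maximum: classes_ is sorted, so ties fall
        # to the alphabetically lowest label
        return self.classes_[np.argmax(scores, axis=1)]


def lda_loocv_single(values, labels) -> float:
    """Leave-one-out accuracy (%) of a single-protein 1-D Gaussian LDA.

    Pooled within-class variance, class-frequency priors; missing values
    enter as 0. Degenerate folds (zero pooled variance) predict the majority
    training class, ties resolving to the alphabetically lowest label.
    """
    x = _zero_fill(np.asarray(values, dtype=float)).ravel()
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("single-marker LDA expects exactly 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("need at least 2 samples per class")
    n = x.size
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xt, yt = x[mask], y[mask]
        correct += _lda1d_predict(xt, yt, classes, x[i]) == y[i]
    return 100.0 * correct / n


def _lda1d_predict(xt, yt, classes, x0) -> object:
    ns = np.array([(yt == c).sum() for c in classes])
    mus = np.array([xt[yt == c].mean() for c in classes])
    ss = sum(((xt[yt == c] - mu) ** 2).sum() for c, mu in zip(classes, mus))
    dof = len(xt) - len(classes)
    var = ss / dof if dof > 0 else 0.0
    if var <= 0:
        # zero-variance limit of LDA: nearest class mean; on a mean tie fall
        # back to the majority class (argmax -> lowest label on a full tie)
        dist = np.abs(x0 - mus)
        nearest = np.flatnonzero(dist == dist.min())
        return classes[nearest[np.argmax(ns[nearest])]]
    priors = ns / ns.sum()
    disc = x0 * mus / var - mus**2 / (2 * var) + np.log(priors)
    return classes[np.argmax(disc)]


def _cv_fold_accuracies(est, X, y, scheme: CVScheme) -> tuple[list[float], pd.DataFrame]:
    """Per-fold accuracies (%) and pooled confusion counts."""
    X = _zero_fill(X)
    y = np.asarray(y)
    classes = np.unique(y)
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    fold_acc: list[float] = []
    for train, test in scheme.splitter(y).split(X, y):
        model = clone(est).fit(X[train], y[train])
        pred = model.predict(X[test])
        fold_acc.append(100.0 * float(np.mean(pred == y[test])))
        for t, p in zip(y[test], pred):
            confusion.loc[t, p] += 1
    return fold_acc, confusion


def pca_lda_cv(
    X, labels, scheme: CVScheme | None = None, variance_kept: float = 0.95
) -> ClassificationReport:
    """Cross-validated PCA-LDA accuracy (standardize/PCA refit per fold)."""
    scheme = scheme or CVScheme()
    est = PCALDAClassifier(variance_kept=variance_kept)
    fold_acc, confusion = _cv_fold_accuracies(est, X, labels, scheme)
    return ClassificationReport(
        model="pca_lda",
        classes=list(np.unique(labels)),
        accuracy=float(np.mean(fold_acc)),
        fold_accuracies=fold_acc,
        confusion=confusion,
    )


def pls_da_cv(
    X, labels, scheme: CVScheme | None = None, max_lv: int = 10
) -> ClassificationReport:
    """Cross-validated PLS-DA accuracy with oneSE latent-variable selection.

    Runs the CV scheme for 1..max_lv latent variables, then selects the
    smallest count whose mean accuracy is within one standard error of the
    best mean accuracy; the report carries the accuracy at that count.
    """
    scheme = scheme or CVScheme()
    X = _zero_fill(X)
    y = np.asarray(labels)
    max_lv = min(max_lv, X.shape[1], X.shape[0] - 2)
    per_lv: list[tuple[list[float], pd.DataFrame]] = []
    for lv in range(1, max_lv + 1):
        per_lv.append(
            _cv_fold_accuracies(PLSDAClassifier(n_components=lv), X, y, scheme)
        )
    means = np.array([np.mean(acc) for acc, _ in per_lv])
    best = int(np.argmax(means))
    best_acc = np.asarray(per_lv[best][0])
    se_best = (
        best_acc.std(ddof=1) / np.sqrt(best_acc.size) if best_acc.size > 1 else 0.0
    )
    selected = int(np.argmax(means >= means[best] - se_best))  # smallest adequate
    fold_acc, confusion = per_lv[selected]
    return ClassificationReport(
        model="pls_da",
        classes=list(np.unique(y)),
        accuracy=float(means[selected]),
        fold_accuracies=fold_acc,
        n_latent=selected + 1,
        confusion=confusion,
    )


def one_se_select(mean_accuracies, se_of_best: float) -> int:
    """Index of the smallest model within one SE of the best mean accuracy."""
    means = np.asarray(mean_accuracies, dtype=float)
    return int(np.argmax(means >= means.max() - se_of_best))


def cross_group_prediction(model, X_third) -> dict:
    """Fractions of held-out third-group samples assigned to each class.

    ``model`` must be final-fit on all samples of its two classes.
    """
    X_third = _zero_fill(X_third)
    if X_third.shape[0] == 0:
        raise ValueError("empty third group")
    pred = model.predict(X_third)
    classes = model.classes_
    return {c: float(np.mean(pred == c)) for c in classes}
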