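"""Diagonal linear discriminant analysis (d-LDA) and cross-validation.

d-LDA is ordinary Gaussian LDA with the pooled within-class covariance
restricted to its diagonal: each feature j contributes an independent
term to the discriminant.  For class k with per-feature means mu_kj,
pooled within-class variances sigma_j^2 and prior pi_k, a sample x is
scored by

    delta_k(x) = sum_j (x_j - mu_kj)^2 / sigma_j^2  -  2 ln pi_k

and assigned to the class minimizing delta_k.  With thousands of
molecules and tens of samples the full covariance is unestimable; the
diagonal restriction is what makes the classifier usable as the inner
engine of a wrapper that fits it millions of times.

Only two-class problems are supported.  Class labels are kept in
lexicographic order; score ties go to the first (smaller) label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CVError, FitError, PredictionError

__all__ = ["DLDAModel", "CVConfig", "CVResult", "fit_dlda", "predict_dlda",
           "cross_validate", "stratified_folds"]

#: relative variance floor: pooled variances are clipped at
#: 1e-12 * max(pooled variance) (or 1e-12 if every variance is zero) so
#: that zero-variance features cannot produce infinite scores.
VARIANCE_FLOOR_REL = 1e-12


@dataclass
class DLDAModel:
    """Fitted two-class diagonal LDA model."""

    feature_ids: list[str]
    class_labels: list[str]            # lexicographically sorted, length 2
    class_means: np.ndarray            # (2, n_features)
    pooled_variances: np.ndarray       # (n_features,), floored
    class_priors: np.ndarray           # (2,), sums to 1
    variance_floor: float

    def __post_init__(self) -> None:
        if len(self.class_labels) != 2:
            raise FitError("d-LDA supports exactly two classes")
        if not np.all(self.pooled_variances >= self.variance_floor):
            raise FitError("pooled variance below floor")
        if not np.isclose(self.class_priors.sum(), 1.0):
            raise FitError("class priors must sum to 1")


@dataclass
class CVConfig:
    """Repeated stratified k-fold cross-validation settings."""

    n_folds: int = 5
    n_repeats: int = 1
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise CVError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise CVError("n_repeats must be >= 1")


@dataclass
class CVResult:
    """Cross-validation metrics, pooled per repeat then averaged."""

    accuracy: float
    per_repeat_accuracy: np.ndarray
    per_fold_accuracy: np.ndarray      # all repeats concatenated
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray              # (2, 2) mean counts per repeat
    positive_class: str

    @property
    def accuracy_se(self) -> float:
        """Standard error of the mean accuracy estimate.

        Uses the spread over repeats when there are several, otherwise
        the spread over folds of the single repeat.
        """
        accs = (self.per_repeat_accuracy if len(self.per_repeat_accuracy) > 1
                else self.per_fold_accuracy)
        if len(accs) < 2:
            return 0.0
        return float(np.std(accs, ddof=1) / np.sqrt(len(accs)))


def _as_matrix(X, feature_ids=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise FitError("X must be 2-dimensional (samples x features)")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(arr.shape[1])]
    return arr, list(feature_ids)


def fit_dlda(X, labels, feature_ids=None, equal_priors: bool = False) -> DLDAModel:
    """Fit a two-class d-LDA model.

    ``X`` is samples x features (DataFrame or array); ``labels`` gives
    the condition of each sample.  Missing values must be imputed by the
    caller (the pipeline imputes 0 after normalization, matching the
    absence semantics of the sparsity filter).
    """
    arr, fids = _as_matrix(X, feature_ids)
    if arr.shape[1] == 0:
        raise FitError("cannot fit d-LDA with zero features")
    if np.isnan(arr).any():
        raise FitError("X contains missing values; impute before fitting")
    y = np.asarray([str(l) for l in labels])
    if len(y) != arr.shape[0]:
        raise FitError("labels length does not match number of samples")
    classes = sorted(set(y))
    if len(classes) != 2:
        raise FitError(f"d-LDA needs exactly 2 classes, got {classes}")
    masks = [y == c for c in classes]
    counts = np.array([m.sum() for m in masks])
    if counts.min() < 2:
        raise FitError("each class needs at least 2 samples")

    means = np.vstack([arr[m].mean(axis=0) for m in masks])
    ss = np.zeros(arr.shape[1])
    for m, mu in zip(masks, means):
        ss += ((arr[m] - mu) ** 2).sum(axis=0)
    pooled = ss / (len(y) - 2)
    vmax = pooled.max() if pooled.size else 0.0
    floor = VARIANCE_FLOOR_REL * (vmax if vmax > 0 else 1.0)
    pooled = np.maximum(pooled, floor)

    priors = (np.array([0.5, 0.5]) if equal_priors
              else counts / counts.sum())
    return DLDAModel(feature_ids=fids, class_labels=classes,
                     class_means=means, pooled_variances=pooled,
                     class_priors=priors, variance_floor=floor)


def predict_dlda(model: DLDAModel, X, feature_ids=None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and discriminant scores for new samples.

    Returns ``(labels, scores)`` where ``scores[i, k]`` is delta_k for
    sample i in the model's class order; the predicted class minimizes
    delta_k, ties going to the lexicographically smaller label.
    """
    arr, fids = _as_matrix(X, feature_ids)
    if fids != model.feature_ids:
        raise PredictionError(
            f"feature mismatch: model has {model.feature_ids}, got {fids}")
    diffs = arr[None, :, :] - model.class_means[:, None, :]   # (2, n, p)
    scores = (diffs ** 2 / model.pooled_variances).sum(axis=2).T  # (n, 2)
    scores -= 2.0 * np.log(model.class_priors)
    pred_idx = np.argmin(scores, axis=1)   # argmin takes first on ties
    labels = np.array(model.class_labels)[pred_idx]
    return labels, scores


def stratified_folds(labels: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Assign each sample a fold in [0, n_folds) stratified by class.

    Within each class the (shuffled) members are dealt round-robin, so
    fold class counts differ by at most one.
    """
    y = np.asarray(labels)
    fold = np.empty(len(y), dtype=int)
    offset = 0
    for c in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == c)
        perm = rng.permutation(idx)
        fold[perm] = (np.arange(len(perm)) + offset) % n_folds
        offset += len(perm)   # stagger classes across folds
    return fold


def _binary_confusion(y_true, y_pred, classes):
    """2x2 counts, rows = true class, cols = predicted class."""
    conf = np.zeros((2, 2))
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            conf[i, j] = np.sum((y_true == ci) & (y_pred == cj))
    return conf


def metrics_from_confusion(conf: np.ndarray, positive_index: int = 1
                           ) -> dict[str, float]:
    """Accuracy / precision / recall / f1 for the positive class."""
    total = conf.sum()
    acc = float(np.trace(conf) / total) if total else 0.0
    p = positive_index
    tp = conf[p, p]
    fp = conf[1 - p, p]
    fn = conf[p, 1 - p]
    precision = float(tp / (tp + fp)) if tp + fp > 0 else 0.0
    recall = float(tp / (tp + fn)) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"accuracy": acc, "precision": precision, "recall": recall, "f1": f1}


def cross_validate(X, labels, panel=None, cv: CVConfig | None = None,
                   positive_class: str | None = None,
                   equal_priors: bool = False) -> CVResult:
    """Repeated stratified k-fold CV of a d-LDA classifier.

    ``X`` is samples x features (DataFrame; ``panel`` selects a column
    subset).  Fold assignment is reshuffled every repeat from a single
    generator seeded with ``cv.seed``, so results are deterministic.
    Metrics are pooled over the folds of a repeat and averaged over
    repeats; the confusion matrix is the mean over repeats, so its
    entries sum to the number of samples.
    """
    cv = cv or CVConfig()
    if panel is not None:
        panel = list(panel)
        if not panel:
            raise CVError("panel must be non-empty")
        missing = [m for m in panel if m not in X.columns]
        if missing:
            raise CVError(f"panel molecules missing from X: {missing}")
        X = X[panel]
    arr, fids = _as_matrix(X)
    y = np.asarray([str(l) for l in labels])
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise CVError(f"cross-validation needs exactly 2 classes, got {classes}")
    min_class = min(np.sum(y == c) for c in classes)
    if cv.n_folds > min_class:
        raise CVError(
            f"n_folds={cv.n_folds} exceeds smallest class size {min_class}")
    if positive_class is None:
        positive_class = classes[1]
    if positive_class not in classes:
        raise CVError(f"positive class {positive_class!r} not among {classes}")
    pos_idx = classes.index(positive_class)

    rng = np.random.default_rng(cv.seed)
    repeat_acc = np.empty(cv.n_repeats)
    fold_acc = []
    conf_sum = np.zeros((2, 2))
    for rep in range(cv.n_repeats):
        fold = stratified_folds(y, cv.n_folds, rng)
        y_pred = np.empty(len(y), dtype=object)
        for f in range(cv.n_folds):
            test = fold == f
            train = ~test
            if len(set(y[train].tolist())) < 2:
                raise CVError("training fold contains a single class")
            model = fit_dlda(arr[train], y[train], feature_ids=fids,
                             equal_priors=equal_priors)
            pred, _ = predict_dlda(model, arr[test], feature_ids=fids)
            y_pred[test] = pred
            fold_acc.append(float(np.mean(pred == y[test])))
        y_pred = y_pred.astype(str)
        conf = _binary_confusion(y, y_pred, classes)
        conf_sum += conf
        repeat_acc[rep] = np.trace(conf) / conf.sum()

    conf_mean = conf_sum / cv.n_repeats
    m = metrics_from_confusion(conf_mean, positive_index=pos_idx)
    return CVResult(accuracy=float(repeat_acc.mean()),
                    per_repeat_accuracy=repeat_acc,
                    per_fold_accuracy=np.array(fold_acc),
                    precision=m["precision"], recall=m["recall"], f1=m["f1"],
                    confusion=conf_mean, positive_class=positive_class)
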