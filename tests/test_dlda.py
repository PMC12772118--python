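import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from panelex import (CVConfig, CVError, FitError, PredictionError,
                     cross_validate, fit_dlda, predict_dlda)
from panelex.dlda import metrics_from_confusion, stratified_folds


def brute_force_scores(model, X):
    """Literal evaluation of delta_k = sum_j (x_j-mu_kj)^2/s_j^2 - 2 ln pi_k."""
    out = np.zeros((len(X), 2))
    for i, x in enumerate(np.asarray(X, float)):
        for k in range(2):
            s = 0.0
            for j in range(len(x)):
                s += (x[j] - model.class_means[k, j]) ** 2 \
                    / model.pooled_variances[j]
            out[i, k] = s - 2.0 * np.log(model.class_priors[k])
    return out


class TestFit:
    def test_zero_within_class_variance_is_floored(self):
        m = fit_dlda(np.array([[0.0], [0.0], [10.0], [10.0]]),
                     ["A", "A", "B", "B"])
        np.testing.assert_allclose(m.class_means[:, 0], [0.0, 10.0])
        assert m.pooled_variances[0] == m.variance_floor > 0

    def test_hand_computed_pooled_variance(self):
        m = fit_dlda(np.array([[1.0], [3.0], [5.0], [7.0]]),
                     ["A", "A", "B", "B"])
        np.testing.assert_allclose(m.class_means[:, 0], [2.0, 6.0])
        np.testing.assert_allclose(m.pooled_variances[0], 2.0)
        np.testing.assert_allclose(m.class_priors, [0.5, 0.5])

    @pytest.mark.parametrize("X,labels", [
        (np.zeros((3, 2)), ["A", "A", "A"]),
        (np.zeros((4, 0)), ["A", "A", "B", "B"]),
        (np.array([[1.0], [np.nan], [2.0], [3.0]]), ["A", "A", "B", "B"]),
        (np.zeros((3, 1)), ["A", "B", "B"]),
    ])
    def test_fit_errors(self, X, labels):
        with pytest.raises(FitError):
            fit_dlda(X, labels)


class TestPredict:
    def setup_method(self):
        self.model = fit_dlda(np.array([[0.0], [0.0], [10.0], [10.0]]),
                              ["A", "A", "B", "B"])

    def test_nearest_mean(self):
        labels, _ = predict_dlda(self.model, np.array([[1.0]]))
        assert labels[0] == "A"

    def test_midpoint_tie_goes_to_smaller_label(self):
        labels, scores = predict_dlda(self.model, np.array([[5.0]]))
        assert scores[0, 0] == scores[0, 1]
        assert labels[0] == "A"

    def test_feature_mismatch_errors(self):
        with pytest.raises(PredictionError):
            predict_dlda(self.model, np.array([[1.0, 2.0]]))

    def test_scores_match_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            X = rng.normal(size=(10, 5))
            y = ["A"] * 5 + ["B"] * 5
            model = fit_dlda(X, y)
            Xq = rng.normal(size=(6, 5))
            _, scores = predict_dlda(model, Xq)
            np.testing.assert_allclose(scores, brute_force_scores(model, Xq),
                                       rtol=1e-12)

    def test_agrees_with_gaussian_likelihood_classifier(self):
        """Independent oracle: argmax of diagonal-Gaussian log-likelihood
        plus log prior equals the discriminant rule."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        y = ["A"] * 8 + ["B"] * 12
        model = fit_dlda(X, y)
        Xq = rng.normal(size=(50, 4))
        pred, _ = predict_dlda(model, Xq)
        sd = np.sqrt(model.pooled_variances)
        loglik = np.stack([
            sps.norm.logpdf(Xq, model.class_means[k], sd).sum(axis=1)
            + np.log(model.class_priors[k]) for k in range(2)])
        oracle = np.array(model.class_labels)[np.argmax(loglik, axis=0)]
        assert (pred == oracle).all()

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 6))
        y = ["A"] * 6 + ["B"] * 6
        perm = rng.permutation(6)
        ids = [f"f{j}" for j in range(6)]
        m1 = fit_dlda(X, y, feature_ids=ids)
        m2 = fit_dlda(X[:, perm], y, feature_ids=[ids[j] for j in perm])
        Xq = rng.normal(size=(7, 6))
        p1, s1 = predict_dlda(m1, Xq, feature_ids=ids)
        p2, s2 = predict_dlda(m2, Xq[:, perm],
                              feature_ids=[ids[j] for j in perm])
        assert (p1 == p2).all()
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_equal_priors_single_feature_boundary_is_midpoint(self):
        m = fit_dlda(np.array([[1.0], [3.0], [6.0], [8.0]]),
                     ["A", "A", "B", "B"], equal_priors=True)
        just_below, _ = predict_dlda(m, np.array([[4.49]]))
        just_above, _ = predict_dlda(m, np.array([[4.51]]))
        assert just_below[0] == "A" and just_above[0] == "B"


class TestCrossValidate:
    def _df(self, X):
        return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])

    def test_perfect_separation_gives_accuracy_one(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 0.1, (15, 1)),
                            rng.normal(10, 0.1, (15, 1))])
        y = ["A"] * 15 + ["B"] * 15
        res = cross_validate(self._df(X), y, cv=CVConfig(seed=1))
        assert res.accuracy == 1.0
        assert res.precision == res.recall == res.f1 == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = ["A"] * 15 + ["B"] * 15
        r1 = cross_validate(self._df(X), y, cv=CVConfig(n_repeats=5, seed=3))
        r2 = cross_validate(self._df(X), y, cv=CVConfig(n_repeats=5, seed=3))
        np.testing.assert_array_equal(r1.per_repeat_accuracy,
                                      r2.per_repeat_accuracy)

    def test_folds_exceeding_class_size_error(self):
        X = np.zeros((6, 1))
        y = ["A", "A", "A", "A", "B", "B"]
        with pytest.raises(CVError):
            cross_validate(self._df(X), y, cv=CVConfig(n_folds=3))

    def test_panel_selects_columns(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(size=(30, 1))
        signal = np.concatenate([rng.normal(0, 0.1, (15, 1)),
                                 rng.normal(9, 0.1, (15, 1))])
        df = pd.DataFrame(np.hstack([noise, signal]), columns=["junk", "good"])
        y = ["A"] * 15 + ["B"] * 15
        res = cross_validate(df, y, panel=["good"], cv=CVConfig(seed=0))
        assert res.accuracy == 1.0
        with pytest.raises(CVError):
            cross_validate(df, y, panel=["absent"], cv=CVConfig(seed=0))


def test_stratified_folds_balanced():
    y = np.array(["A"] * 10 + ["B"] * 15)
    fold = stratified_folds(y, 5, np.random.default_rng(0))
    for f in range(5):
        assert (fold[:10] == f).sum() == 2
        assert (fold[10:] == f).sum() == 3


def test_metrics_from_confusion_hand_example():
    m = metrics_from_confusion(np.array([[3.0, 1.0], [1.0, 3.0]]),
                               positive_index=1)
    assert m == {"accuracy": 0.75, "precision": 0.75,
                 "recall": 0.75, "f1": 0.75}
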