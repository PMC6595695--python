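"""Clinical-validation pipeline: splitting, Fisher score, SVM, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest

from gaitphase.core import ParameterError, ValidationError
from gaitphase.validation import (
    ValidationConfig,
    balance_training,
    binarize_labels,
    fisher_score,
    roc_auc,
    run_validation,
    select_top_k,
    split_train_test,
    tune_and_fit_svm,
)


class TestBinarize:
    def test_nonzero_scores_are_impaired(self):
        np.testing.assert_array_equal(binarize_labels([0, 1, 0, 2]), [0, 1, 0, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            binarize_labels([0, 5])


class TestSplit:
    def test_stratified_arithmetic(self):
        labels = np.array([0] * 5 + [1] * 5)
        train, test = split_train_test(10, labels, 0.6, seed=0)
        assert len(train) == 6 and len(test) == 4
        assert np.sum(labels[train]) == 3 and np.sum(labels[test]) == 2

    def test_disjoint_and_exhaustive(self):
        labels = np.array([0] * 7 + [1] * 9)
        train, test = split_train_test(16, labels, 0.6, seed=1)
        assert sorted(np.concatenate([train, test]).tolist()) == list(range(16))

    def test_same_seed_same_split(self):
        labels = np.array([0, 1] * 10)
        assert np.array_equal(
            split_train_test(20, labels, 0.6, seed=5)[0],
            split_train_test(20, labels, 0.6, seed=5)[0],
        )


class TestBalance:
    def test_majority_undersampled_to_minority(self):
        labels = np.array([0] * 31 + [1] * 20)
        idx = balance_training(np.arange(51), labels, seed=0)
        assert np.sum(labels[idx] == 0) == 20 and np.sum(labels[idx] == 1) == 20

    def test_already_balanced_unchanged(self):
        labels = np.array([0] * 10 + [1] * 10)
        idx = balance_training(np.arange(20), labels, seed=0)
        assert np.array_equal(idx, np.arange(20))

    def test_deterministic(self):
        labels = np.array([0] * 9 + [1] * 4)
        a = balance_training(np.arange(13), labels, seed=3)
        b = balance_training(np.arange(13), labels, seed=3)
        assert np.array_equal(a, b)


class TestFisherScore:
    def test_hand_formula(self):
        # class means 1 and 4, sample variances (ddof=1) both 2 -> 9/4
        x = np.array([0, 2, 3, 5], dtype=float)
        y = np.array([0, 0, 1, 1])
        assert fisher_score(x, y) == pytest.approx(2.25)

    def test_identical_distributions_score_zero(self):
        x = np.array([1.0, 2.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        assert fisher_score(x, y) == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2], y[-2:] = 0, 1  # ensure both classes
        base = fisher_score(x, y)
        assert fisher_score(3.5 * x - 2.0, y) == pytest.approx(base)

    def test_zero_variance_classes(self):
        y = np.array([0, 0, 1, 1])
        assert fisher_score([1.0, 1.0, 2.0, 2.0], y) == np.inf
        assert fisher_score([1.0, 1.0, 1.0, 1.0], y) == 0.0


class TestSelectTopK:
    def _table(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 10 + [1] * 10)
        data = {f"noise{j}": rng.normal(size=20) for j in range(3)}
        for j in range(5):
            data[f"signal{j}"] = rng.normal(size=20) + y * (5 - j)
        return pd.DataFrame(data), y

    def test_discriminating_features_selected(self):
        df, y = self._table()
        selected = select_top_k(df, y, k=5)
        assert set(selected) == {f"signal{j}" for j in range(5)}

    def test_k_equal_to_feature_count_selects_all(self):
        df, y = self._table()
        assert set(select_top_k(df, y, k=df.shape[1])) == set(df.columns)

    def test_ties_break_toward_earlier_column(self):
        y = np.array([0, 0, 1, 1])
        df = pd.DataFrame({"a": [0, 2, 3, 5], "b": [0, 2, 3, 5], "c": [0, 0, 0, 0]})
        assert select_top_k(df, y, k=1) == ["a"]

    def test_missing_values_imputed_by_median(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        df = pd.DataFrame({"x": [0.0, np.nan, 3.0, 5.0, 1.0, 4.0], "z": np.zeros(6)})
        assert select_top_k(df, y, k=1) == ["x"]


class TestRocAuc:
    def test_perfect_and_inverted_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.3] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pairwise_oracle_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert roc_auc(scores, labels) == wins / (len(pos) * len(neg))

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(3)
        scores = rng.permutation(20) / 20.0
        labels = np.array([0, 1] * 10)
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(1.0)


class TestSvmTuning:
    def test_separable_blobs_reach_high_cv_auc(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        config = ValidationConfig(seed=0)
        _, best, cv_auc = tune_and_fit_svm(x, y, config)
        assert cv_auc >= 0.99

    def test_deterministic_best_pair(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 3))
        y = np.array([0, 1] * 15)
        config = ValidationConfig(seed=7)
        _, best1, _ = tune_and_fit_svm(x, y, config)
        _, best2, _ = tune_and_fit_svm(x, y, config)
        assert best1 == best2


def _feature_cohort(n=60, n_features=8, effect=2.0, n_signal=3, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    data = {}
    for j in range(n_features):
        x = rng.normal(size=n)
        if j < n_signal:
            x = x + labels * effect
        data[f"f{j}"] = x
    scores = labels.copy()  # clinical sub-score 0/1
    return pd.DataFrame(data), scores


class TestRunValidation:
    def test_informative_features_classify_well(self):
        feats, scores = _feature_cohort(seed=1)
        config = ValidationConfig(seed=2)
        result = run_validation(feats, scores, "constant", "distr vel", config)
        assert result.test_auc >= 0.9
        assert len(result.selected_features) == 5

    def test_result_is_deterministic(self):
        feats, scores = _feature_cohort(seed=3)
        config = ValidationConfig(seed=4)
        a = run_validation(feats, scores, "constant", "x", config)
        b = run_validation(feats, scores, "constant", "x", config)
        assert a.test_auc == b.test_auc and a.selected_features == b.selected_features

    def test_mutating_test_rows_leaves_model_untouched(self):
        feats, scores = _feature_cohort(seed=5)
        config = ValidationConfig(seed=6)
        labels = binarize_labels(scores)
        train_idx, test_idx = split_train_test(len(feats), labels, 0.6, config.seed)
        ref = run_validation(feats, scores, "c", "m", config)
        corrupted = feats.copy()
        corrupted.iloc[test_idx] = corrupted.iloc[test_idx] * 13.0 + 7.0
        alt = run_validation(corrupted, scores, "c", "m", config)
        assert alt.selected_features == ref.selected_features
        assert (alt.best_c, alt.best_gamma) == (ref.best_c, ref.best_gamma)
        assert alt.cv_auc == ref.cv_auc

    def test_excessive_missingness_aborts(self):
        feats, scores = _feature_cohort(n=20, seed=7)
        feats.iloc[:10] = np.nan
        with pytest.raises(Exception, match="missing"):
            run_validation(feats, scores, "turning", "m", ValidationConfig(seed=0))
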