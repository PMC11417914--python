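import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from deamipred.chimeric_model import FeatureSet
from deamipred.errors import ValidationError
from deamipred.evaluation import (
    ConfusionMatrix,
    compute_metrics,
    cross_validate,
    roc_auc,
    roc_points,
    stratified_kfold,
    window_sweep,
)
from deamipred.io_formats import RunConfig


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert m.accuracy == m.precision == m.recall == m.specificity == m.f1 == 1.0
        assert m.mcc == 1.0

    def test_zero_denominator_conventions(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0 and m.mcc == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=1)

    @settings(max_examples=200, deadline=None)
    @given(
        tp=st.integers(0, 200), fp=st.integers(0, 200),
        fn=st.integers(0, 200), tn=st.integers(0, 200),
    )
    def test_matches_sklearn(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        m = compute_metrics(ConfusionMatrix(tp, fp, fn, tn))
        assert m.accuracy == pytest.approx(skm.accuracy_score(y_true, y_pred))
        assert m.precision == pytest.approx(
            skm.precision_score(y_true, y_pred, zero_division=0))
        assert m.recall == pytest.approx(skm.recall_score(y_true, y_pred, zero_division=0))
        assert m.f1 == pytest.approx(skm.f1_score(y_true, y_pred, zero_division=0))
        # sklearn returns 0 for degenerate MCC as we do
        assert m.mcc == pytest.approx(skm.matthews_corrcoef(y_true, y_pred), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 100), fp=st.integers(0, 100),
        fn=st.integers(0, 100), tn=st.integers(0, 100),
    )
    def test_mcc_class_swap_invariance(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        a = compute_metrics(ConfusionMatrix(tp, fp, fn, tn)).mcc
        b = compute_metrics(ConfusionMatrix(tn, fn, fp, tp)).mcc
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounds(self):
        m = compute_metrics(ConfusionMatrix(3, 9, 2, 1))
        for v in (m.accuracy, m.precision, m.recall, m.specificity, m.f1):
            assert 0.0 <= v <= 1.0
        assert -1.0 <= m.mcc <= 1.0


def auc_pair_counting(scores, labels):
    """Exhaustive oracle: mean over active x inactive pairs, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_string_labels(self):
        assert roc_auc([0.9, 0.1], ["active", "inactive"]) == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(2, 20))
        scores = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False).map(lambda x: round(x, 2)),
            min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(labels) in (0, n):
            return
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels) == pytest.approx(
            skm.roc_auc_score(labels, scores), abs=1e-12)


def test_roc_points_monotone():
    rng = np.random.default_rng(1)
    scores = np.round(rng.random(50), 1)
    labels = rng.integers(0, 2, 50)
    df = roc_points(scores, labels)
    assert df["fpr"].is_monotonic_increasing
    assert df["tpr"].is_monotonic_increasing
    assert df.iloc[-1]["fpr"] == 1.0 and df.iloc[-1]["tpr"] == 1.0


class TestStratifiedKFold:
    def test_partition_property(self):
        y = np.array([1] * 12 + [0] * 88)
        folds = stratified_kfold(y, 5, seed=0)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(100))
        for a, b in itertools.combinations(folds, 2):
            assert not set(a) & set(b)

    def test_100_sites_12_active(self):
        y = np.array([1] * 12 + [0] * 88)
        for fold in stratified_kfold(y, 5, seed=3):
            assert len(fold) == 20
            assert y[fold].sum() in (2, 3)

    def test_exact_stratification_small(self):
        y = np.array([1, 0, 1, 0])
        folds = stratified_kfold(y, 2, seed=0)
        for fold in folds:
            assert len(fold) == 2 and y[fold].sum() == 1

    def test_class_smaller_than_k(self):
        with pytest.raises(ValidationError, match="fewer than k"):
            stratified_kfold(np.array([1, 0, 0, 0, 0]), 3, seed=0)

    def test_k_below_two(self):
        with pytest.raises(ValidationError):
            stratified_kfold(np.array([1, 0]), 1, seed=0)

    def test_seeded_determinism(self):
        y = np.array([1] * 10 + [0] * 30)
        a = stratified_kfold(y, 4, seed=9)
        b = stratified_kfold(y, 4, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def cv_result(self, small_features, fast_config):
        return cross_validate(small_features, "global_only", fast_config, k=3)

    def test_fold_count_and_aggregates(self, cv_result):
        assert len(cv_result.per_fold) == 3
        mccs = [r.mcc for r in cv_result.per_fold]
        assert cv_result.mean["mcc"] == pytest.approx(np.mean(mccs))
        assert cv_result.sd["mcc"] == pytest.approx(np.std(mccs, ddof=1))

    def test_seeded_determinism(self, small_features, fast_config, cv_result):
        again = cross_validate(small_features, "global_only", fast_config, k=3)
        assert again.mean == cv_result.mean

    def test_requires_labels(self, small_features, fast_config):
        unlabeled = FeatureSet(small_features.X_global, small_features.tokens,
                               small_features.provenance, "mock", small_features.window_size)
        with pytest.raises(ValidationError):
            cross_validate(unlabeled, "global_only", fast_config, k=3)


class TestWindowSweep:
    def test_single_size(self, small_dataset, fast_config):
        from deamipred.chimeric_model import featurize_labeled
        from deamipred.global_embedding import make_mock_embedder
        from deamipred.labeling import label_sites

        chains, sites, _ = small_dataset
        labeled = label_sites(sites)
        feats = {3: featurize_labeled(labeled, chains, make_mock_embedder(16, 0), 3)}
        result = window_sweep(feats, fast_config, k=3)
        assert list(result.table["window_size"]) == [3]
        assert result.best_size == 3

    def test_even_size_rejected(self, small_features, fast_config):
        with pytest.raises(ValidationError):
            window_sweep({4: small_features}, fast_config, k=2)
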