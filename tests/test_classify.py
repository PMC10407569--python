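"""Feature building, balancing, model fitting, metrics and importance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

import mirlit
from mirlit.classify import ConfusionMatrix, MODEL_NAMES

from conftest import make_doc


def tagged(title, pmid="1"):
    return mirlit.tag_document(make_doc(pmid, title=title))


def toy_matrix(n=20, noise_cols=0, seed=0):
    """Feature equal to the label: perfectly separable."""
    rng = np.random.default_rng(seed)
    labels = np.array([1, 0] * (n // 2))
    cols = {"signal": labels}
    for j in range(noise_cols):
        cols[f"noise{j}"] = rng.integers(0, 2, size=n)
    return mirlit.FeatureMatrix(pd.DataFrame(cols), labels)


class TestBuildFeatureMatrix:
    def test_presence_encoding(self):
        pos = [tagged("miR-21 study", "1")]
        neg = [tagged("no mirna here", "2")]
        mat = mirlit.build_feature_matrix(pos, neg, vocabulary=["miR-21", "miR-146"])
        assert list(mat.values.loc["1"]) == [1, 0]
        assert list(mat.values.loc["2"]) == [0, 0]
        assert list(mat.labels) == [1, 0]

    def test_repeated_mentions_stay_binary(self):
        pos = [tagged("miR-21, miR-21-5p and miR21 again", "1")]
        mat = mirlit.build_feature_matrix(pos, [tagged("x", "2")])
        assert mat.values.loc["1", "miR-21"] == 1

    def test_default_vocabulary_is_union(self):
        pos = [tagged("miR-1", "1")]
        neg = [tagged("miR-2", "2")]
        mat = mirlit.build_feature_matrix(pos, neg)
        assert list(mat.values.columns) == ["miR-1", "miR-2"]

    def test_empty_vocabulary_raises(self):
        with pytest.raises(ValueError):
            mirlit.build_feature_matrix([tagged("nothing", "1")], [tagged("none", "2")])


class TestBalanceClasses:
    def test_downsamples_larger_class(self):
        pos = mirlit.Corpus([make_doc(str(i)) for i in range(5)])
        neg = mirlit.Corpus([make_doc(str(100 + i)) for i in range(50)])
        p, n = mirlit.balance_classes(pos, neg, seed=0)
        assert len(p) == len(n) == 5

    def test_equal_classes_unchanged(self):
        pos = mirlit.Corpus([make_doc(str(i)) for i in range(5)])
        neg = mirlit.Corpus([make_doc(str(100 + i)) for i in range(5)])
        p, n = mirlit.balance_classes(pos, neg, seed=0)
        assert [d.pmid for d in p] == [d.pmid for d in pos]
        assert [d.pmid for d in n] == [d.pmid for d in neg]

    def test_seed_determinism(self):
        pos = mirlit.Corpus([make_doc(str(i)) for i in range(3)])
        neg = mirlit.Corpus([make_doc(str(100 + i)) for i in range(30)])
        first = [d.pmid for d in mirlit.balance_classes(pos, neg, seed=9)[1]]
        second = [d.pmid for d in mirlit.balance_classes(pos, neg, seed=9)[1]]
        assert first == second

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            mirlit.balance_classes(mirlit.Corpus([]), mirlit.Corpus([make_doc("1")]))


class TestHoldoutSplit:
    def test_sizes_and_disjoint(self):
        mat = toy_matrix(n=100)
        train, test = mirlit.holdout_split(mat, mirlit.SplitConfig(test_fraction=0.3, seed=0))
        assert len(test.labels) == 30 and len(train.labels) == 70
        assert not set(train.values.index) & set(test.values.index)

    def test_stratified_balance(self):
        mat = toy_matrix(n=100)
        _, test = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=1))
        counts = np.bincount(test.labels)
        assert abs(counts[0] - counts[1]) <= 1

    def test_seed_determinism(self):
        mat = toy_matrix(n=40)
        a = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=3))[1].values.index
        b = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=3))[1].values.index
        assert list(a) == list(b)

    def test_tiny_class_raises(self):
        labels = np.array([1] * 9 + [0])
        mat = mirlit.FeatureMatrix(pd.DataFrame({"f": labels}), labels)
        with pytest.raises(ValueError):
            mirlit.holdout_split(mat, mirlit.SplitConfig())


class TestFitPredict:
    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_separable_data_perfect_accuracy(self, model):
        mat = toy_matrix(n=20)
        train, test = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=0))
        _, pred, scores = mirlit.fit_predict(
            mirlit.ClassifierConfig(model=model, seed=0), train, test
        )
        assert (pred == test.labels).all()
        assert len(scores) == len(test.labels)

    def test_all_zero_features_majority_rate(self):
        labels = np.array([1, 0] * 20)
        mat = mirlit.FeatureMatrix(pd.DataFrame({"f": np.zeros(40, dtype=int)}), labels)
        train, test = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=0))
        _, pred, _ = mirlit.fit_predict(mirlit.ClassifierConfig(model="DT", seed=0), train, test)
        assert abs((pred == test.labels).mean() - 0.5) <= 0.1

    def test_svm_default_hyperparameters(self):
        mat = toy_matrix(n=20)
        train, test = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=0))
        model, _, _ = mirlit.fit_predict(mirlit.ClassifierConfig(model="SVM", seed=0), train, test)
        assert model.C == 10 and model.gamma == "scale" and model.kernel == "sigmoid"

    def test_single_class_training_raises(self):
        labels = np.ones(10, dtype=int)
        mat = mirlit.FeatureMatrix(pd.DataFrame({"f": labels}), labels)
        with pytest.raises(ValueError):
            mirlit.fit_predict(mirlit.ClassifierConfig(model="NB"), mat, mat)


class TestMetrics:
    def test_perfect_classifier(self):
        m = mirlit.metrics_from_confusion(ConfusionMatrix(tp=1, fp=0, fn=0, tn=1))
        assert m.accuracy == m.mcc == m.f_score == 1

    def test_worked_example(self):
        m = mirlit.metrics_from_confusion(ConfusionMatrix(tp=30, fp=10, fn=20, tn=40))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f_score == pytest.approx(0.6667, abs=5e-5)
        assert m.mcc == pytest.approx(0.4082, abs=5e-5)

    def test_zero_denominator_flagged_not_zero(self):
        m = mirlit.metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert math.isnan(m.precision)
        assert m.accuracy == 0.5

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_agrees_with_bruteforce_recount(self, tp, fp, fn, tn):
        """Metrics from counts match a recount from raw (label, prediction) pairs."""
        if tp + fp + fn + tn == 0:
            return
        labels = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        preds = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        cm = ConfusionMatrix.from_predictions(labels, preds)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        m = mirlit.metrics_from_confusion(cm)
        acc = sum(l == p for l, p in zip(labels, preds)) / len(labels)
        assert m.accuracy == pytest.approx(acc)


class TestRocAuc:
    def test_perfect_scores(self):
        _, _, auc = mirlit.roc_auc([1, 0, 1, 0], [1.0, 0.0, 1.0, 0.0])
        assert auc == 1.0

    def test_pairwise_concordance_example(self):
        _, _, auc = mirlit.roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert auc == pytest.approx(0.75)

    def test_constant_scores_chance(self):
        _, _, auc = mirlit.roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mirlit.roc_auc([1, 1], [0.2, 0.3])

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 30), st.integers(2, 30))
    def test_equals_normalized_mann_whitney_u(self, seed, n_pos, n_neg):
        """AUC is the Mann-Whitney U statistic divided by n_pos * n_neg."""
        rng = np.random.default_rng(seed)
        labels = np.array([1] * n_pos + [0] * n_neg)
        scores = rng.integers(0, 10, size=n_pos + n_neg).astype(float)  # ties likely
        _, _, auc = mirlit.roc_auc(labels, scores)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / (n_pos * n_neg))


class TestPermutationImportance:
    def test_signal_feature_strictly_largest(self):
        mat = toy_matrix(n=60, noise_cols=4, seed=1)
        train, test = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=1))
        model, _, _ = mirlit.fit_predict(mirlit.ClassifierConfig(model="RF", seed=1), train, test)
        imp = mirlit.permutation_importance(model, test, n_repeats=10, seed=1)
        assert imp.index[0] == "signal"
        assert imp.iloc[0] > imp.iloc[1]

    def test_constant_column_zero_importance(self):
        mat = toy_matrix(n=40, noise_cols=0, seed=0)
        mat.values["constant"] = 1
        train, test = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=0))
        model, _, _ = mirlit.fit_predict(mirlit.ClassifierConfig(model="DT", seed=0), train, test)
        imp = mirlit.permutation_importance(model, test, n_repeats=5, seed=0)
        assert imp["constant"] == 0

    def test_seed_determinism(self, signal_run):
        again = mirlit.permutation_importance(
            signal_run["model"], signal_run["test"], n_repeats=20, seed=42
        )
        pd.testing.assert_series_equal(again, signal_run["importance"])

    def test_matches_reference_implementation(self):
        """Cross-check against the accuracy-scoring reference routine."""
        from sklearn.inspection import permutation_importance as sk_importance

        mat = toy_matrix(n=60, noise_cols=3, seed=2)
        train, test = mirlit.holdout_split(mat, mirlit.SplitConfig(seed=2))
        model, _, _ = mirlit.fit_predict(mirlit.ClassifierConfig(model="RF", seed=2), train, test)
        ours = mirlit.permutation_importance(model, test, n_repeats=30, seed=2)
        ref = sk_importance(
            model, test.values.to_numpy(), test.labels,
            scoring="accuracy", n_repeats=30, random_state=2,
        )
        ref_means = dict(zip(test.values.columns, ref.importances_mean))
        for name in ours.index:
            assert ours[name] == pytest.approx(ref_means[name], abs=0.05)


class TestTopKMirnas:
    def test_ranking_by_document_count(self):
        corpus = [
            tagged("miR-21 and miR-1", "1"),
            tagged("miR-21 again", "2"),
            tagged("nothing", "3"),
        ]
        assert mirlit.top_k_mirnas(corpus, 2) == [("miR-21", 2), ("miR-1", 1)]

    def test_k_larger_than_distinct(self):
        corpus = [tagged("miR-5", "1")]
        assert mirlit.top_k_mirnas(corpus, 10) == [("miR-5", 1)]

    def test_per_doc_duplicates_do_not_inflate(self):
        corpus = [tagged("miR-7 miR-7 miR-7-5p", "1")]
        assert mirlit.top_k_mirnas(corpus, 1) == [("miR-7", 1)]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            mirlit.top_k_mirnas([], 0)


def test_evaluate_models_reports_all_metrics(signal_run):
    table = mirlit.evaluate_models(
        signal_run["matrix"], mirlit.SplitConfig(seed=42), models=("NB",), seed=42
    )
    assert set(table.columns) == {"accuracy", "recall", "precision", "mcc", "f_score", "auc"}
    assert table.loc["NB", "accuracy"] > 0.8
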