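"""Document classification from miRNA presence features.

A document is represented by which core miRNA names appear in it (binary
presence, deduplicated per document).  Case documents (e.g. diabetes
studies) are paired with an equal number of down-sampled controls, split
once into train/test (holdout), and classified with one of four model
families: Bernoulli naive Bayes, decision tree, random forest, or a
support-vector machine (defaults C=10, gamma="scale", kernel="sigmoid").
Reported metrics are accuracy, recall, precision, MCC, F-score and AUC;
per-feature relevance is measured by permutation importance on held-out
accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .corpus_io import Corpus
from .mirna_tagging import TaggedDocument

MODEL_NAMES = ("NB", "DT", "RF", "SVM")


@dataclass
class FeatureMatrix:
    """Documents x miRNA-core binary presence with class labels (1=case, 0=control)."""

    values: pd.DataFrame  # rows: documents (index pmid), columns: cores
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("labels do not match rows")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature columns")


@dataclass
class SplitConfig:
    test_fraction: float = 0.3
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0,1)")


@dataclass
class ClassifierConfig:
    model: str = "SVM"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_predictions(cls, labels: Sequence[int], predicted: Sequence[int]) -> "ConfusionMatrix":
        labels = np.asarray(labels)
        predicted = np.asarray(predicted)
        return cls(
            tp=int(np.sum((labels == 1) & (predicted == 1))),
            fp=int(np.sum((labels == 0) & (predicted == 1))),
            fn=int(np.sum((labels == 1) & (predicted == 0))),
            tn=int(np.sum((labels == 0) & (predicted == 0))),
        )


@dataclass
class ClassifierMetrics:
    accuracy: float
    recall: float
    precision: float
    mcc: float
    f_score: float
    auc: float = float("nan")


# ---------------------------------------------------------------------------
# Feature construction and balancing
# ---------------------------------------------------------------------------

def build_feature_matrix(
    tagged_pos: Sequence[TaggedDocument],
    tagged_neg: Sequence[TaggedDocument],
    vocabulary: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Binary presence matrix over normalized miRNA cores.

    ``vocabulary`` defaults to the union of cores observed across both
    corpora; multiple mentions of one core in a document still contribute a
    single 1 (per-document dedup).
    """
    if vocabulary is None:
        vocabulary = sorted(
            {c for td in list(tagged_pos) + list(tagged_neg) for c in td.mirna_set}
        )
    vocabulary = list(vocabulary)
    if not vocabulary:
        raise ValueError("empty feature vocabulary")
    rows, labels, index = [], [], []
    for label, group in ((1, tagged_pos), (0, tagged_neg)):
        for td in group:
            rows.append([1 if c in td.mirna_set else 0 for c in vocabulary])
            labels.append(label)
            index.append(td.document.pmid)
    values = pd.DataFrame(rows, columns=vocabulary, index=index, dtype=np.int8)
    return FeatureMatrix(values=values, labels=np.array(labels))


def balance_classes(pos: Corpus, neg: Corpus, seed: int = 0) -> tuple[Corpus, Corpus]:
    """Down-sample the larger class uniformly without replacement.

    Returns the two corpora at equal size ``min(|pos|, |neg|)``; the
    selection is deterministic for a given seed.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)

    def sample(corpus: Corpus, n: int) -> Corpus:
        if len(corpus) == n:
            return corpus
        idx = sorted(rng.choice(len(corpus), size=n, replace=False))
        return Corpus([corpus.documents[i] for i in idx], label=corpus.label)

    n = min(len(pos), len(neg))
    return sample(pos, n), sample(neg, n)


def holdout_split(
    matrix: FeatureMatrix, config: SplitConfig
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Single stratified (by default) train/test partition."""
    stratify = matrix.labels if config.stratified else None
    if config.stratified:
        counts = np.bincount(matrix.labels, minlength=2)
        if counts.min() < 2:
            raise ValueError("need >= 2 rows per class for a stratified split")
    train_idx, test_idx = train_test_split(
        np.arange(len(matrix.labels)),
        test_size=config.test_fraction,
        random_state=config.seed,
        stratify=stratify,
    )
    return (
        FeatureMatrix(matrix.values.iloc[train_idx], matrix.labels[train_idx]),
        FeatureMatrix(matrix.values.iloc[test_idx], matrix.labels[test_idx]),
    )


# ---------------------------------------------------------------------------
# Model fitting and evaluation
# ---------------------------------------------------------------------------

def _make_model(config: ClassifierConfig):
    hp = dict(config.hyperparameters)
    if config.model == "NB":
        return BernoulliNB(**hp)
    if config.model == "DT":
        return DecisionTreeClassifier(random_state=config.seed, **hp)
    if config.model == "RF":
        return RandomForestClassifier(random_state=config.seed, **hp)
    hp.setdefault("C", 10)
    hp.setdefault("gamma", "scale")
    hp.setdefault("kernel", "sigmoid")
    return SVC(random_state=config.seed, **hp)


def fit_predict(
    config: ClassifierConfig, train: FeatureMatrix, test: FeatureMatrix
):
    """Fit one model family; return (fitted model, predicted labels, scores).

    Scores are decision-function values for the SVM and positive-class
    probabilities for the other families.
    """
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data contains a single class")
    model = _make_model(config)
    model.fit(train.values.to_numpy(), train.labels)
    X = test.values.to_numpy()
    predicted = model.predict(X)
    if hasattr(model, "decision_function"):
        scores = model.decision_function(X)
    else:
        scores = model.predict_proba(X)[:, 1]
    return model, predicted, scores


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassifierMetrics:
    """Accuracy, recall, precision, MCC and F-score from confusion counts.

    A metric whose denominator is zero is reported as NaN (undefined), never
    silently as 0.
    """
    n = cm.tp + cm.fp + cm.fn + cm.tn
    accuracy = (cm.tp + cm.tn) / n if n else float("nan")
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else float("nan")
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else float("nan")
    if math.isnan(recall) or math.isnan(precision) or precision + recall == 0:
        f_score = float("nan")
    else:
        f_score = 2 * precision * recall / (precision + recall)
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = (
        (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom) if denom else float("nan")
    )
    return ClassifierMetrics(
        accuracy=accuracy, recall=recall, precision=precision, mcc=mcc, f_score=f_score
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]):
    """ROC points and AUC.

    AUC equals the probability that a random positive outscores a random
    negative, with ties counting one half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return fpr, tpr, float(_auc(fpr, tpr))


def permutation_importance(
    model,
    test: FeatureMatrix,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Mean drop in held-out accuracy when one feature column is shuffled.

    For each feature, the column is permuted ``n_repeats`` times and the
    importance is the average (baseline accuracy - permuted accuracy).
    Returned sorted descending; deterministic for a fixed seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    X = test.values.to_numpy().copy()
    y = test.labels
    baseline = float(np.mean(model.predict(X) == y))
    importances = {}
    for j, name in enumerate(test.values.columns):
        drops = np.empty(n_repeats)
        original = X[:, j].copy()
        for r in range(n_repeats):
            X[:, j] = rng.permutation(original)
            drops[r] = baseline - float(np.mean(model.predict(X) == y))
        X[:, j] = original
        importances[name] = float(drops.mean())
    return pd.Series(importances).sort_values(ascending=False, kind="stable")


def top_k_mirnas(tagged_corpus: Sequence[TaggedDocument], k: int) -> list[tuple[str, int]]:
    """Cores ranked by the number of documents mentioning them (ties lexicographic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for td in tagged_corpus:
        for core in td.mirna_set:
            counts[core] = counts.get(core, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def evaluate_models(
    matrix: FeatureMatrix,
    split: SplitConfig,
    models: Sequence[str] = MODEL_NAMES,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/evaluate each model family on one holdout split.

    Returns a table with one row per model: accuracy, recall, precision,
    MCC, F-score and AUC, reported to full precision (format to 4 decimals
    for display).
    """
    train, test = holdout_split(matrix, split)
    rows = []
    for name in models:
        _, predicted, scores = fit_predict(
            ClassifierConfig(model=name, seed=seed), train, test
        )
        m = metrics_from_confusion(ConfusionMatrix.from_predictions(test.labels, predicted))
        _, _, auc_value = roc_auc(test.labels, scores)
        rows.append(
            {
                "model": name,
                "accuracy": m.accuracy,
                "recall": m.recall,
                "precision": m.precision,
                "mcc": m.mcc,
                "f_score": m.f_score,
                "auc": auc_value,
            }
        )
    return pd.DataFrame(rows).set_index("model")
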