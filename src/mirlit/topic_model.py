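"""LDA topic modeling of abstracts and topic association matrices.

Documents are modeled as mixtures of latent topics and topics as
distributions over vocabulary terms.  The fitted model yields a
document-topic matrix (theta) and a topic-term matrix (phi); from the
per-document *dominant topic* (argmax of theta) we derive topic-by-year
publication counts and miRNA-by-topic association counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from .corpus_io import Corpus, default_stopwords
from .mirna_tagging import TaggedDocument, tokenize


@dataclass
class TopicModelConfig:
    """LDA configuration.

    ``n_topics`` defaults to 13, the number of themes resolved in diabetes
    miRNA literature at corpus scale; for synthetic or small corpora pass an
    appropriate value.  ``doc_topic_prior``/``topic_word_prior`` of ``None``
    mean the fitting routine's defaults (1/n_topics each).
    """

    n_topics: int = 13
    doc_topic_prior: Optional[float] = None
    topic_word_prior: Optional[float] = None
    max_iterations: int = 100
    min_df: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")


@dataclass
class TopicModelResult:
    theta: np.ndarray  # documents x topics, rows sum to 1
    phi: np.ndarray  # topics x vocabulary, rows sum to 1
    vocabulary: list[str]
    config: TopicModelConfig
    perplexity: float = field(default=float("nan"))


def _lda_tokenizer(text: str) -> list[str]:
    return [t for t in tokenize(text) if len(t) > 1]


def build_document_term_matrix(texts: Sequence[str], min_df: int = 2):
    """Count matrix over lowercased, stopword-filtered, hyphen-preserving tokens."""
    vectorizer = CountVectorizer(
        lowercase=True,
        tokenizer=_lda_tokenizer,
        token_pattern=None,
        stop_words=list(default_stopwords()),
        min_df=min_df,
    )
    counts = vectorizer.fit_transform(texts)
    return counts, list(vectorizer.get_feature_names_out())


def fit_lda(texts: Sequence[str], config: TopicModelConfig) -> TopicModelResult:
    """Fit LDA by batch variational Bayes; deterministic for a fixed seed.

    ``texts`` are raw document strings (title+abstract); the vocabulary is
    built here with lowercasing, stopword removal and a minimum document
    frequency of ``config.min_df``.
    """
    if len(texts) < config.n_topics:
        raise ValueError("need at least n_topics documents")
    counts, vocabulary = build_document_term_matrix(texts, min_df=config.min_df)
    if counts.shape[1] == 0:
        raise ValueError("vocabulary empty after filtering")
    lda = LatentDirichletAllocation(
        n_components=config.n_topics,
        doc_topic_prior=config.doc_topic_prior,
        topic_word_prior=config.topic_word_prior,
        max_iter=config.max_iterations,
        learning_method="batch",
        random_state=config.seed,
    )
    theta = lda.fit_transform(counts)
    theta = theta / theta.sum(axis=1, keepdims=True)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModelResult(
        theta=theta,
        phi=phi,
        vocabulary=vocabulary,
        config=config,
        perplexity=float(lda.perplexity(counts)),
    )


def dominant_topic(theta: np.ndarray) -> np.ndarray:
    """1-based dominant topic per document; ties break to the lowest index."""
    return np.argmax(theta, axis=1) + 1


def top_terms(phi: np.ndarray, vocabulary: Sequence[str], k: int) -> list[list[str]]:
    """Per topic, the ``k`` highest-weight terms (ties lexicographic)."""
    if k > len(vocabulary):
        raise ValueError("k exceeds vocabulary size")
    result = []
    for row in phi:
        order = sorted(zip(row, vocabulary), key=lambda wv: (-wv[0], wv[1]))
        result.append([term for _, term in order[:k]])
    return result


def topic_year_matrix(result: TopicModelResult, corpus: Corpus) -> pd.DataFrame:
    """Topics x years counts of documents by dominant topic.

    Documents without a parseable year are omitted; the matrix total equals
    the number of documents with a known year.
    """
    if len(corpus) != result.theta.shape[0]:
        raise ValueError("corpus size does not match fitted model")
    topics = dominant_topic(result.theta)
    rows = [
        (t, y)
        for t, doc in zip(topics, corpus)
        if (y := doc.year()) is not None
    ]
    n_topics = result.config.n_topics
    if not rows:
        return pd.DataFrame(index=pd.RangeIndex(1, n_topics + 1, name="topic"))
    years = sorted({y for _, y in rows})
    mat = pd.DataFrame(
        0, index=pd.RangeIndex(1, n_topics + 1, name="topic"), columns=years
    )
    for t, y in rows:
        mat.loc[t, y] += 1
    return mat


def mirna_topic_matrix(
    result: TopicModelResult, tagged_corpus: Sequence[TaggedDocument]
) -> pd.DataFrame:
    """miRNA cores x topics: documents with dominant topic t mentioning core m."""
    if len(tagged_corpus) != result.theta.shape[0]:
        raise ValueError("tagged corpus size does not match fitted model")
    topics = dominant_topic(result.theta)
    cores = sorted({c for td in tagged_corpus for c in td.mirna_set})
    n_topics = result.config.n_topics
    mat = pd.DataFrame(
        0, index=pd.Index(cores, name="mirna"), columns=range(1, n_topics + 1)
    )
    for t, td in zip(topics, tagged_corpus):
        for core in td.mirna_set:
            mat.loc[core, t] += 1
    return mat
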