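"""Shared fixtures: tiny format fixtures and session-scoped synthetic runs."""

from __future__ import annotations

import numpy as np
import pytest

import mirlit

MEDLINE_TEXT = """\
PMID- 1
DP  - 2020
TI  - T.
AB  - A
PT  - Journal Article

PMID- 2
DP  - 2019 Mar
TI  - miR-21 in diabetic kidney disease.
AB  - We studied miR-21 and miR-21-3p in DKD patients.
PT  - Journal Article
PT  - Comparative Study

"""

PUBTATOR_TEXT = """\
1|t|miR-21 in kidney
1|a|IRAK1 was repressed.
1\t0\t6\tmiR-21\tGene\tmir21
1\t17\t22\tIRAK1\tGene\t3654

2|t|No annotations here
2|a|

"""


@pytest.fixture()
def medline_file(tmp_path):
    path = tmp_path / "corpus.medline"
    path.write_text(MEDLINE_TEXT)
    return path


@pytest.fixture()
def pubtator_file(tmp_path):
    path = tmp_path / "corpus.pubtator"
    path.write_text(PUBTATOR_TEXT)
    return path


def make_doc(pmid="1", title="", abstract="", date="2020", types=("Journal Article",)):
    return mirlit.Document(
        pmid=pmid,
        title=title,
        abstract=abstract,
        pub_date=date,
        pub_types=frozenset(types),
    )


@pytest.fixture(scope="session")
def signal_run():
    """Full classification pipeline on the default planted-signal corpus.

    1,000 documents per class, five signal miRNAs at Bernoulli 0.6 (case)
    vs 0.1 (control), literature-scale background vocabulary; holdout 0.3;
    sigmoid-kernel SVM with C=10 and permutation importance (20 repeats).
    """
    config = mirlit.SynthConfig(seed=42)
    corpus, truth = mirlit.generate_corpus(config)
    pos, neg = mirlit.split_by_label(corpus, truth)
    matrix = mirlit.build_feature_matrix(mirlit.tag_corpus(pos), mirlit.tag_corpus(neg))
    train, test = mirlit.holdout_split(matrix, mirlit.SplitConfig(seed=42))
    model, predicted, scores = mirlit.fit_predict(
        mirlit.ClassifierConfig(model="SVM", seed=42), train, test
    )
    importance = mirlit.permutation_importance(model, test, n_repeats=20, seed=42)
    return {
        "config": config,
        "corpus": corpus,
        "truth": truth,
        "matrix": matrix,
        "test": test,
        "model": model,
        "accuracy": float(np.mean(predicted == test.labels)),
        "scores": scores,
        "importance": importance,
    }


@pytest.fixture(scope="session")
def lda_run():
    """LDA fit on 500 case documents with three planted topics.

    Topic modeling runs on the disease corpus alone, as in the analysis this
    emulates.  One miRNA (let-950) is planted only in topic-2 documents, so
    the topic-association matrix has known structure.
    """
    config = mirlit.SynthConfig(
        n_docs_per_class=500,
        seed=42,
        topic_mirnas={2: [("let-950", 0.8)]},
    )
    full_corpus, truth = mirlit.generate_corpus(config)
    case, _ = mirlit.split_by_label(full_corpus, truth)
    result = mirlit.fit_lda(
        [d.text for d in case], mirlit.TopicModelConfig(n_topics=3, seed=42)
    )
    return {"config": config, "corpus": case, "truth": truth, "result": result}


def topic_confusion(truth, corpus, dominant, n_topics):
    """Planted-vs-fitted dominant topic contingency table."""
    C = np.zeros((n_topics, n_topics))
    for doc, fitted in zip(corpus, dominant):
        C[truth.topics[doc.pmid] - 1, fitted - 1] += 1
    return C
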