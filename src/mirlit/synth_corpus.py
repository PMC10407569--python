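"""Synthetic labeled literature corpora with known ground truth.

Generates case/control document sets that statistically resemble a
disease-focused miRNA literature: abstracts are bags of words drawn from a
planted topic's keyword pool mixed with shared filler vocabulary
(high-frequency tokens such as "mirna", "expression", "patient"); each
configured miRNA is mentioned with a class-conditional Bernoulli
probability and rendered through realistic surface-form variation (prefix
variants, species prefixes, letter/arm suffixes, case styles); optional
PubTator-style gene annotations are planted for co-mention analyses.  The
generator records every planted label, topic and mention span, so tagger
recall/precision, topic recovery and classifier accuracy can be scored
against truth.

Synthetic miRNA numbers are drawn from 900-999 so they cannot collide with
real literature names in mixed tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus, Document, EntityAnnotation

_CORE = re.compile(r"^(miR|let)-(\d+)$")

#: Surface-form variant families and their default sampling weights.
#: All default families are recoverable by the recognition pattern.
DEFAULT_SURFACE_WEIGHTS = {
    "plain": 0.30,        # miR-155
    "mirna": 0.10,        # miRNA-155
    "microrna": 0.10,     # microRNA-155
    "nohyphen": 0.10,     # miR155
    "species": 0.15,      # hsa-miR-155
    "letter": 0.10,       # miR-155a
    "arm": 0.10,          # miR-155-5p
    "upper": 0.025,       # MIR-155
    "lower": 0.025,       # mir-155
}

#: Keyword pools for the default three planted topics (pairwise disjoint).
DEFAULT_TOPIC_POOLS = (
    (
        "inflammation", "cytokine", "macrophage", "nfkb", "stroke",
        "neuropathy", "signaling", "receptor", "immune", "response",
    ),
    (
        "metabolism", "glucose", "insulin", "lipid", "obesity",
        "adipose", "resistance", "homeostasis", "secretion", "hepatic",
    ),
    (
        "kidney", "nephropathy", "renal", "fibrosis", "podocyte",
        "glomerular", "albuminuria", "creatinine", "tubular", "mesangial",
    ),
)

#: Shared filler vocabulary mirroring the high-frequency tokens of real
#: abstracts, so term-frequency summaries have a known top set.
DEFAULT_FILLER = (
    "mirna", "expression", "patient", "study", "level", "cell",
    "analysis", "group", "result", "target", "role", "pathway",
)


def default_background_mirnas() -> tuple[tuple[str, float], ...]:
    """Literature-scale background miRNA vocabulary with long-tailed rates.

    Real corpora mention many distinct miRNAs, a few frequently and most
    rarely; the default plants 94 class-neutral miRNAs whose per-document
    mention probabilities decay from 0.15 as 1/sqrt(rank), giving roughly
    two or three incidental mentions per abstract.
    """
    cores = [f"miR-{n}" for n in range(906, 996)] + [f"let-{n}" for n in range(996, 1000)]
    return tuple(
        (core, round(0.15 / (i + 1) ** 0.5, 4)) for i, core in enumerate(cores)
    )


@dataclass
class SynthConfig:
    """Study conditions for corpus generation.

    Defaults plant five signal miRNAs mentioned in 60% of case documents
    versus 10% of controls, three well-separated topics, and the word
    "diabetes" at high rate in case abstracts.
    """

    n_docs_per_class: int = 1000
    n_topics: int = 3
    topic_pools: Sequence[Sequence[str]] = DEFAULT_TOPIC_POOLS
    filler: Sequence[str] = DEFAULT_FILLER
    signal_mirnas: Sequence[tuple[str, float, float]] = (
        ("miR-901", 0.6, 0.1),
        ("miR-902", 0.6, 0.1),
        ("miR-903", 0.6, 0.1),
        ("miR-904", 0.6, 0.1),
        ("miR-905", 0.6, 0.1),
    )
    background_mirnas: Sequence[tuple[str, float]] = field(
        default_factory=lambda: default_background_mirnas()
    )
    #: miRNAs planted only in documents of a given topic: {topic: [(core, p)]}
    topic_mirnas: dict[int, Sequence[tuple[str, float]]] = field(default_factory=dict)
    #: genes annotated (PubTator-style) whenever a core is mentioned:
    #: {core: [(gene_symbol, probability)]}
    gene_annotations: dict[str, Sequence[tuple[str, float]]] = field(default_factory=dict)
    words_per_abstract: tuple[int, int] = (30, 60)
    topic_word_fraction: float = 0.7
    case_term: str = "diabetes"
    case_term_rate: float = 0.3
    surface_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SURFACE_WEIGHTS))
    adversarial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if len(self.topic_pools) < self.n_topics:
            raise ValueError("need a keyword pool per topic")
        pools = [set(p) for p in self.topic_pools[: self.n_topics]]
        for i in range(len(pools)):
            for j in range(i + 1, len(pools)):
                if pools[i] & pools[j]:
                    raise ValueError("topic keyword pools must be pairwise disjoint")
        for probs in (
            [p for _, p, q in self.signal_mirnas] + [q for _, p, q in self.signal_mirnas]
        ):
            if not 0 <= probs <= 1:
                raise ValueError("probabilities must be in [0,1]")


@dataclass
class PlantedMention:
    core: str
    surface: str
    span_start: int
    span_end: int


@dataclass
class GroundTruth:
    """Per-document truth: class label, planted topic, planted mentions."""

    labels: dict[str, int] = field(default_factory=dict)
    topics: dict[str, int] = field(default_factory=dict)  # 1-based
    mentions: dict[str, list[PlantedMention]] = field(default_factory=dict)

    def mirna_sets(self) -> dict[str, frozenset[str]]:
        return {
            pmid: frozenset(m.core for m in ms) for pmid, ms in self.mentions.items()
        }


def sample_surface_form(
    core: str,
    rng: np.random.Generator,
    weights: Optional[dict[str, float]] = None,
    adversarial: bool = False,
) -> str:
    """Render a core name ("miR-155", "let-7") as one realistic surface form.

    Default variant families all normalize back to the input core;
    ``adversarial`` adds the historical "lin-4" form, which the standard
    nomenclature pattern does not cover (for negative testing).
    """
    m = _CORE.match(core)
    if not m:
        raise ValueError(f"malformed core name: {core!r}")
    prefix, number = m.groups()
    weights = dict(weights or DEFAULT_SURFACE_WEIGHTS)
    if prefix == "let":
        # prefix-variant families do not apply to let-N names
        for key in ("mirna", "microrna"):
            weights.pop(key, None)
    if adversarial:
        weights["lin4"] = 0.1
    names = sorted(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    variant = names[rng.choice(len(names), p=probs / probs.sum())]
    letter = "abcde"[int(rng.integers(5))]
    arm = ("-3p", "-5p")[int(rng.integers(2))]
    if variant == "lin4":
        return "lin-4"
    if prefix == "let":
        forms = {
            "plain": f"let-{number}",
            "nohyphen": f"let{number}",
            "species": f"hsa-let-{number}",
            "letter": f"let-{number}{letter}",
            "arm": f"let-{number}{letter}{arm}",
            "upper": f"LET-{number}",
            "lower": f"let-{number}",
        }
    else:
        forms = {
            "plain": f"miR-{number}",
            "mirna": f"miRNA-{number}",
            "microrna": f"microRNA-{number}",
            "nohyphen": f"miR{number}",
            "species": f"hsa-miR-{number}",
            "letter": f"miR-{number}{letter}",
            "arm": f"miR-{number}{arm}",
            "upper": f"MIR-{number}",
            "lower": f"mir-{number}",
        }
    return forms[variant]


def _planted_cores(config: SynthConfig, label: int, topic: int, rng) -> list[str]:
    cores = []
    for core, p_case, p_control in config.signal_mirnas:
        if rng.random() < (p_case if label == 1 else p_control):
            cores.append(core)
    for core, p in config.background_mirnas:
        if rng.random() < p:
            cores.append(core)
    for core, p in config.topic_mirnas.get(topic, ()):
        if rng.random() < p:
            cores.append(core)
    return cores


def generate_corpus(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a labeled corpus and its ground truth; seed-deterministic.

    Case documents get pmids "1000000+i" and label 1, controls "2000000+i"
    and label 0.  Every abstract is a bag of topic-pool and filler words
    with planted miRNA surface forms (and optionally annotated gene
    symbols) interspersed; all spans index ``title + " " + abstract``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.words_per_abstract
    for pool in config.topic_pools[: config.n_topics]:
        if not pool:
            raise ValueError("empty keyword pool")
    documents: list[Document] = []
    truth = GroundTruth()
    for label, base in ((1, 1_000_000), (0, 2_000_000)):
        for i in range(config.n_docs_per_class):
            pmid = str(base + i)
            topic = int(rng.integers(config.n_topics)) + 1
            pool = list(config.topic_pools[topic - 1])
            filler = list(config.filler)

            n_words = int(rng.integers(lo, hi + 1))
            words: list[tuple[str, str]] = []  # (token, kind)
            for _ in range(n_words):
                if rng.random() < config.topic_word_fraction:
                    words.append((pool[int(rng.integers(len(pool)))], "w"))
                elif label == 1 and rng.random() < config.case_term_rate:
                    words.append((config.case_term, "w"))
                else:
                    words.append((filler[int(rng.integers(len(filler)))], "w"))

            cores = _planted_cores(config, label, topic, rng)
            for core in cores:
                surface = sample_surface_form(
                    core, rng, config.surface_weights, adversarial=config.adversarial
                )
                pos = int(rng.integers(len(words) + 1))
                words.insert(pos, (surface, f"m:{core}"))
                for gene, p in config.gene_annotations.get(core, ()):
                    if rng.random() < p:
                        pos = int(rng.integers(len(words) + 1))
                        words.insert(pos, (gene, "g"))

            title = f"{pool[int(rng.integers(len(pool)))]} {config.case_term if label == 1 else 'cohort'} study"
            year = 2006 + int(rng.integers(18))
            doc = Document(
                pmid=pmid,
                title=title,
                pub_date=str(year),
                pub_types=frozenset({"Journal Article"}),
            )
            # assemble abstract and record spans in title+" "+abstract
            offset = len(title) + 1
            parts, mentions = [], []
            for token, kind in words:
                start = offset
                end = offset + len(token)
                if kind.startswith("m:"):
                    mentions.append(PlantedMention(kind[2:], token, start, end))
                elif kind == "g":
                    doc.annotations.append(
                        EntityAnnotation(start, end, token, "gene", f"synth:{token}")
                    )
                parts.append(token)
                offset = end + 1
            doc.abstract = " ".join(parts)
            documents.append(doc)
            truth.labels[pmid] = label
            truth.topics[pmid] = topic
            truth.mentions[pmid] = mentions
    return Corpus(documents), truth


def split_by_label(corpus: Corpus, truth: GroundTruth) -> tuple[Corpus, Corpus]:
    """Separate a generated corpus into (case, control) sub-corpora."""
    pos = [d for d in corpus if truth.labels[d.pmid] == 1]
    neg = [d for d in corpus if truth.labels[d.pmid] == 0]
    return Corpus(pos, label=1), Corpus(neg, label=0)


def ground_truth_report(truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Truth tables: labels, planted topics, planted mentions with spans."""
    labels = pd.DataFrame(
        sorted(truth.labels.items()), columns=["pmid", "label"]
    )
    topics = pd.DataFrame(
        sorted(truth.topics.items()), columns=["pmid", "topic"]
    )
    rows = [
        (pmid, m.core, m.surface, m.span_start, m.span_end)
        for pmid, ms in sorted(truth.mentions.items())
        for m in ms
    ]
    mentions = pd.DataFrame(
        rows, columns=["pmid", "core", "surface", "span_start", "span_end"]
    )
    return {"labels": labels, "topics": topics, "mentions": mentions}


def save_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in ground_truth_report(truth).items():
        table.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)
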