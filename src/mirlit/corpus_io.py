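"""Reading, filtering and summarising literature corpora.

Two on-disk formats are supported: the MEDLINE flat-file format produced by
PubMed exports (tag-value lines such as ``PMID-``, ``TI  -``, ``AB  -``) and
the PubTator annotation format (``PMID|t|title`` / ``PMID|a|abstract`` lines
followed by tab-separated entity annotations).  Both are loaded into a single
in-memory :class:`Corpus` of :class:`Document` records so every downstream
stage is format-agnostic.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Medline

logger = logging.getLogger("mirlit")

#: Entity types PubTator emits; free text is tolerated but these are canonical.
ENTITY_TYPES = {"gene", "disease", "species", "chemical", "cellline", "mutation"}

#: Default publication-type inclusion list.  "Clinical Trail" is kept alongside
#: the corrected "Clinical Trial" spelling so both forms are accepted.
DEFAULT_INCLUDE_TYPES = frozenset(
    {
        "case reports",
        "clinical study",
        "clinical trail",
        "clinical trial",
        "comparative study",
        "english abstract",
        "evaluation study",
        "journal article",
        "letter",
        "preprint",
    }
)

#: Default publication-type exclusion list (reviews, errata, editorial matter).
DEFAULT_EXCLUDE_TYPES = frozenset(
    {
        "retraction of publication",
        "published erratum",
        "editorial",
        "news",
        "dataset",
        "clinical trial protocol",
        "review",
        "systematic review",
    }
)


@dataclass(frozen=True)
class EntityAnnotation:
    """A pre-computed entity span over ``title + " " + abstract``."""

    span_start: int
    span_end: int
    surface: str
    entity_type: str
    concept_id: str = ""

    def overlaps(self, start: int, end: int) -> bool:
        return self.span_start < end and start < self.span_end


@dataclass
class Document:
    """One literature record (title/abstract plus PubMed metadata)."""

    pmid: str
    title: str = ""
    abstract: str = ""
    pub_date: str = ""
    pub_types: frozenset[str] = field(default_factory=frozenset)
    annotations: list[EntityAnnotation] = field(default_factory=list)
    first_author: str = ""
    journal: str = ""

    @property
    def text(self) -> str:
        """Title and abstract concatenated with a single space separator."""
        if self.abstract:
            return f"{self.title} {self.abstract}"
        return self.title

    def year(self) -> Optional[int]:
        """First four-digit year found in ``pub_date``, or ``None``."""
        m = re.search(r"\b(\d{4})\b", self.pub_date)
        return int(m.group(1)) if m else None


@dataclass
class Corpus:
    """Ordered, pmid-unique collection of documents with an optional class label."""

    documents: list[Document] = field(default_factory=list)
    label: Optional[int] = None

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def __post_init__(self) -> None:
        pmids = [d.pmid for d in self.documents]
        if len(pmids) != len(set(pmids)):
            raise ValueError("duplicate pmid in Corpus")


# ---------------------------------------------------------------------------
# MEDLINE flat-file I/O
# ---------------------------------------------------------------------------

def read_medline(path: str | Path) -> Corpus:
    """Read a MEDLINE flat file into a :class:`Corpus`.

    Continuation lines are joined with single spaces (Bio.Medline semantics);
    a record with no PMID is skipped with a warning, as is any record whose
    PMID repeats an earlier one.
    """
    documents: list[Document] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in Medline.parse(handle):
            pmid = rec.get("PMID", "").strip()
            if not pmid:
                logger.warning("MEDLINE record without PMID skipped")
                continue
            if pmid in seen:
                logger.warning("duplicate PMID %s: record dropped", pmid)
                continue
            seen.add(pmid)
            documents.append(
                Document(
                    pmid=pmid,
                    title=_strip_period(rec.get("TI", "")),
                    abstract=rec.get("AB", ""),
                    pub_date=rec.get("DP", ""),
                    pub_types=frozenset(rec.get("PT", [])),
                    first_author=(rec.get("AU") or [""])[0],
                    journal=rec.get("JT", ""),
                )
            )
    return Corpus(documents)


def write_medline(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in MEDLINE flat-file format (inverse of :func:`read_medline`)."""
    with open(path, "w") as out:
        for doc in corpus:
            lines = [f"PMID- {doc.pmid}"]
            if doc.pub_date:
                lines.append(f"DP  - {doc.pub_date}")
            if doc.title:
                lines.append(f"TI  - {doc.title}.")
            if doc.abstract:
                lines.append(f"AB  - {doc.abstract}")
            for pt in sorted(doc.pub_types):
                lines.append(f"PT  - {pt}")
            if doc.first_author:
                lines.append(f"AU  - {doc.first_author}")
            if doc.journal:
                lines.append(f"JT  - {doc.journal}")
            out.write("\n".join(lines) + "\n\n")


def _strip_period(title: str) -> str:
    # PubMed terminates TI fields with a period not part of the title proper.
    return title[:-1] if title.endswith(".") else title


# ---------------------------------------------------------------------------
# PubTator format
# ---------------------------------------------------------------------------

_PUBTATOR_TEXT = re.compile(r"^(\S+)\|([ta])\|(.*)$")


def read_pubtator(path: str | Path) -> Corpus:
    """Read a PubTator-format file (title/abstract lines plus annotation TSV).

    Annotation spans index into ``title + " " + abstract``.  An annotation
    whose surface does not equal the text slice at its span is dropped with a
    warning; a structurally malformed line raises with its line number.
    """
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    raw_annotations: dict[str, list[tuple[int, int, str, str, str]]] = {}
    order: list[str] = []

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = _PUBTATOR_TEXT.match(line)
            if m:
                pmid, kind, text = m.groups()
                if pmid not in titles and pmid not in abstracts:
                    order.append(pmid)
                (titles if kind == "t" else abstracts)[pmid] = text
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"malformed PubTator line {lineno}: {line!r}")
            pmid, start_s, end_s, surface, etype = fields[:5]
            concept = fields[5] if len(fields) > 5 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed PubTator line {lineno}: {line!r}") from exc
            raw_annotations.setdefault(pmid, []).append(
                (start, end, surface, etype, concept)
            )

    documents = []
    seen: set[str] = set()
    for pmid in order:
        if pmid in seen:
            logger.warning("duplicate PMID %s: record dropped", pmid)
            continue
        seen.add(pmid)
        doc = Document(pmid=pmid, title=titles.get(pmid, ""), abstract=abstracts.get(pmid, ""))
        text = doc.text
        for start, end, surface, etype, concept in raw_annotations.get(pmid, []):
            if not (0 <= start < end <= len(text)) or text[start:end] != surface:
                logger.warning(
                    "PMID %s: annotation span (%d,%d,%r) does not match text; dropped",
                    pmid, start, end, surface,
                )
                continue
            doc.annotations.append(
                EntityAnnotation(start, end, surface, etype.lower(), concept)
            )
        documents.append(doc)
    return Corpus(documents)


def write_pubtator(corpus: Corpus, path: str | Path) -> None:
    """Write documents (and any annotations) in PubTator format."""
    with open(path, "w") as out:
        for doc in corpus:
            out.write(f"{doc.pmid}|t|{doc.title}\n")
            out.write(f"{doc.pmid}|a|{doc.abstract}\n")
            for ann in doc.annotations:
                out.write(
                    f"{doc.pmid}\t{ann.span_start}\t{ann.span_end}\t"
                    f"{ann.surface}\t{ann.entity_type}\t{ann.concept_id}\n"
                )
            out.write("\n")


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------

def filter_publication_types(
    corpus: Corpus,
    include: Iterable[str] = DEFAULT_INCLUDE_TYPES,
    exclude: Iterable[str] = DEFAULT_EXCLUDE_TYPES,
) -> Corpus:
    """Retain documents matching the inclusion list and none of the exclusions.

    A document is kept iff at least one of its publication types is in
    ``include`` and none is in ``exclude``.  Matching is case-insensitive
    exact string comparison (PubMed PT values are controlled vocabulary).
    """
    inc = {s.lower() for s in include}
    exc = {s.lower() for s in exclude}
    kept = [
        doc
        for doc in corpus
        if (types := {t.lower() for t in doc.pub_types}) & inc and not types & exc
    ]
    return Corpus(kept, label=corpus.label)


def yearly_counts(corpus: Corpus) -> dict:
    """Documents per publication year; unparseable dates fall in ``"unknown"``."""
    counts: Counter = Counter()
    for doc in corpus:
        year = doc.year()
        if year is None:
            logger.warning("PMID %s: unparseable date %r", doc.pmid, doc.pub_date)
            counts["unknown"] += 1
        else:
            counts[year] += 1
    return dict(sorted(counts.items(), key=lambda kv: (isinstance(kv[0], str), kv[0])))


def term_frequency_table(
    corpus: Corpus, stopwords: Optional[Iterable[str]] = None
) -> list[tuple[str, int]]:
    """Corpus-wide token counts after lowercasing and stopword removal.

    Tokenization matches :func:`mirlit.mirna_tagging.tokenize` (hyphen
    preserving).  Returned sorted by descending count, ties lexicographic.
    """
    from .mirna_tagging import tokenize

    if stopwords is None:
        stopwords = default_stopwords()
    stop = {s.lower() for s in stopwords}
    counts: Counter = Counter()
    for doc in corpus:
        for token in tokenize(doc.text):
            token = token.lower()
            if token not in stop and len(token) > 1:
                counts[token] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def default_stopwords() -> frozenset[str]:
    """The standard English stopword list used across the pipeline."""
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

    return frozenset(ENGLISH_STOP_WORDS)


def save_frequency_table(table: Sequence[tuple], path: str | Path, header=("token", "count")) -> None:
    with open(path, "w") as out:
        out.write("\t".join(header) + "\n")
        for row in table:
            out.write("\t".join(str(v) for v in row) + "\n")
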