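"""miRNA mention recognition and nomenclature normalization.

miRNA names follow a tight convention — a prefix ("miR", "microRNA",
"miRNA", "micro-RNA", or the historical "let") plus an identifying number,
optionally decorated with a species prefix ("hsa-"), a letter suffix
("-146a"), a genomic-copy suffix ("-1".."-5"), and an arm suffix
("-3p"/"-5p").  Recognition is a single regular expression applied tokenwise
after hyphen-preserving tokenization; every matched surface form is reduced
to a *core name* ("miR-146", "let-7") so that "miR-155", "microRNA-155",
"miR155" and "miR-155-5p" all count as one miRNA, at most once per document.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

from .corpus_io import Corpus, Document

#: Recognition pattern over single tokens: miR/microRNA/miRNA variants
#: (with optional letter, genomic-copy and arm suffixes) or let-N variants.
MIRNA_PATTERN = re.compile(
    r"[Mm][Ii][Cc]?[Rr][Oo]?[Rr]?[Nn]?[Aa]?-?\d+[a-zA-Z]?-?[12345]?-?[35]?[Pp]?"
    r"|[Ll][Ee][Tt]-?\d+[a-zA-Z]?-?[35]?[Pp]?"
)

#: Strict variant: requires a full "miR"/"miRNA"/"microRNA"/"micro-RNA"/"let"
#: prefix instead of the permissive optional groups above.
STRICT_PATTERN = re.compile(
    r"(?:[Mm][Ii][Cc][Rr][Oo]-?[Rr][Nn][Aa]|[Mm][Ii][Rr](?:[Nn][Aa])?)"
    r"-?\d+[a-zA-Z]?-?[12345]?-?[35]?[Pp]?"
    r"|[Ll][Ee][Tt]-?\d+[a-zA-Z]?-?[35]?[Pp]?"
)

#: Historical exception "lin-4", not covered by the nomenclature pattern.
LIN4_PATTERN = re.compile(r"[Ll][Ii][Nn]-?4")

_TOKEN = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9-]*[A-Za-z0-9])?")

_LET_HEAD = re.compile(r"^[Ll][Ee][Tt]")
_LIN_HEAD = re.compile(r"^[Ll][Ii][Nn]")


@dataclass(frozen=True)
class MirnaMention:
    surface: str
    span_start: int
    span_end: int
    core: str


@dataclass
class TaggedDocument:
    document: Document
    mentions: list[MirnaMention] = field(default_factory=list)

    @property
    def mirna_set(self) -> frozenset[str]:
        """Core names, deduplicated: a miRNA counts once per document."""
        return frozenset(m.core for m in self.mentions)


def tokenize(text: str) -> list[str]:
    """Split on whitespace and punctuation, preserving internal hyphens.

    >>> tokenize("miR-146a-5p regulates IRAK1.")
    ['miR-146a-5p', 'regulates', 'IRAK1']
    """
    return _TOKEN.findall(text)


def _token_spans(text: str) -> Iterator[tuple[int, str]]:
    for m in _TOKEN.finditer(text):
        yield m.start(), m.group()


def find_mirna_mentions(
    text: str, strict: bool = False, include_lin4: bool = False
) -> list[MirnaMention]:
    """All miRNA mentions in ``text``, with character spans and core names.

    The pattern is applied per token so that a species prefix ("hsa-") does
    not block recognition inside "hsa-miR-21"; within a token, matches are
    leftmost and greedy (longest for the matching alternative), so
    "miR-146a-5p" yields one mention, not a partial one.
    """
    pattern = STRICT_PATTERN if strict else MIRNA_PATTERN
    mentions: list[MirnaMention] = []
    for offset, token in _token_spans(text):
        for m in pattern.finditer(token):
            mentions.append(
                MirnaMention(
                    surface=m.group(),
                    span_start=offset + m.start(),
                    span_end=offset + m.end(),
                    core=normalize_core(m.group()),
                )
            )
        if include_lin4:
            for m in LIN4_PATTERN.finditer(token):
                mentions.append(
                    MirnaMention(m.group(), offset + m.start(), offset + m.end(), "lin-4")
                )
    mentions.sort(key=lambda x: (x.span_start, x.span_end))
    return mentions


def normalize_core(surface: str) -> str:
    """Reduce a recognized surface form to its core name.

    The prefix collapses to "miR" (or "let"/"lin" for the historical
    exceptions), the identifying number is the first digit run, and any
    species prefix, letter suffix, genomic-copy suffix or arm suffix is
    discarded:

    >>> normalize_core("miR155"), normalize_core("hsa-miR-21-5p"), normalize_core("LET-7B")
    ('miR-155', 'miR-21', 'let-7')
    """
    s = surface
    # species prefixes like "hsa-" may arrive if the caller matched raw text
    s = re.sub(r"^[a-z]{3,4}-(?=[MmLl])", "", s)
    digits = re.search(r"\d+", s)
    if digits is None:
        raise ValueError(f"not a recognizable miRNA surface form: {surface!r}")
    if _LET_HEAD.match(s):
        prefix = "let"
    elif _LIN_HEAD.match(s):
        prefix = "lin"
    elif s[:1] in "Mm":
        prefix = "miR"
    else:
        raise ValueError(f"not a recognizable miRNA surface form: {surface!r}")
    return f"{prefix}-{digits.group()}"


def tag_document(
    document: Document, strict: bool = False, include_lin4: bool = False
) -> TaggedDocument:
    """Tag a document's title+abstract; mentions ordered by span."""
    mentions = find_mirna_mentions(document.text, strict=strict, include_lin4=include_lin4)
    return TaggedDocument(document=document, mentions=mentions)


def tag_corpus(
    corpus: Corpus, strict: bool = False, include_lin4: bool = False
) -> list[TaggedDocument]:
    return [tag_document(d, strict=strict, include_lin4=include_lin4) for d in corpus]


def validate_against_gene_annotations(tagged: TaggedDocument) -> dict:
    """QC report: regex mentions not overlapping any gene-type annotation.

    Used to cross-check the regex tagger against pre-computed gene NER.  No
    filtering happens here — the report lists the unsupported mentions, or
    flags the document when it carries no annotations at all.
    """
    gene_spans = [
        (a.span_start, a.span_end)
        for a in tagged.document.annotations
        if a.entity_type == "gene"
    ]
    if not tagged.document.annotations:
        return {"status": "no-annotation", "unsupported": list(tagged.mentions)}
    unsupported = [
        m
        for m in tagged.mentions
        if not any(s < m.span_end and m.span_start < e for s, e in gene_spans)
    ]
    return {"status": "ok", "unsupported": unsupported}
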