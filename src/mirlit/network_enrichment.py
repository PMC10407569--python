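"""Gene co-mention matrices, target-list intersection, and pathway ORA.

For a chosen miRNA core, the studies mentioning it are collected and the
genes annotated in their titles/abstracts form a binary gene-by-study
presence matrix.  Those co-mentioned genes are intersected with a predicted
target list (TargetScan-style TSV) to flag direct targets, and tested for
pathway over-representation against a GMT gene-set collection with the
one-sided hypergeometric test and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mirna_tagging import MIRNA_PATTERN, TaggedDocument

logger = logging.getLogger("mirlit")


@dataclass
class TargetList:
    mirna_family: str
    targets: frozenset[str]  # uppercased gene symbols


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # columns: pathway, size, overlap, genes, p, fdr

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


def gene_presence_matrix(
    tagged_corpus: Sequence[TaggedDocument],
    mirna_core: str,
    min_docs: int = 2,
) -> pd.DataFrame:
    """Binary genes x documents matrix for studies mentioning ``mirna_core``.

    Gene symbols come from the documents' gene-type annotations (uppercased
    surfaces); rows are kept only for genes present in at least ``min_docs``
    documents, and annotation surfaces that are themselves miRNA names are
    excluded from the gene rows.
    """
    docs = [td for td in tagged_corpus if mirna_core in td.mirna_set]
    if not docs:
        raise ValueError(f"no documents mention {mirna_core}")
    presence: dict[str, set[str]] = {}
    pmids = [td.document.pmid for td in docs]
    for td in docs:
        for ann in td.document.annotations:
            if ann.entity_type != "gene":
                continue
            if MIRNA_PATTERN.search(ann.surface):
                continue
            symbol = ann.surface.upper()
            presence.setdefault(symbol, set()).add(td.document.pmid)
    rows = sorted(g for g, ds in presence.items() if len(ds) >= min_docs)
    mat = pd.DataFrame(0, index=pd.Index(rows, name="gene"), columns=pmids, dtype=int)
    for g in rows:
        for pmid in presence[g]:
            mat.loc[g, pmid] = 1
    return mat


def read_target_list(path: str | Path, mirna_family: str) -> TargetList:
    """Read a TargetScan-style TSV of (miR family, target gene symbol, ...).

    The header row is auto-detected; family matching is case-insensitive and
    tolerant of arm/species decorations in the family column (a row matches
    if its family field contains the requested core).
    """
    targets: set[str] = set()
    family_lc = mirna_family.lower()
    with open(path) as handle:
        for i, line in enumerate(handle):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                continue
            if i == 0 and not re.search(r"\d", fields[0]):
                continue  # header
            family, gene = fields[0], fields[1]
            if family_lc in family.lower():
                targets.add(gene.strip().upper())
    return TargetList(mirna_family=mirna_family, targets=frozenset(targets))


def intersect_target_list(
    gene_rows: Iterable[str], targets: TargetList
) -> frozenset[str]:
    """Co-mentioned genes that are also predicted targets (case-insensitive)."""
    if not targets.targets:
        logger.warning("empty target list for %s", targets.mirna_family)
        return frozenset()
    rows = {g.upper() for g in gene_rows}
    return frozenset(rows & targets.targets)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name = fields[0]
            sets[name] = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
    return sets


def ora_hypergeometric(
    query: Iterable[str],
    collection: dict[str, frozenset[str]],
    universe: Optional[Iterable[str]] = None,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation analysis.

    For each gene set S the p-value is P(X >= |query & S|) drawing |query|
    genes from a universe containing |S & universe| successes; p-values are
    Benjamini-Hochberg adjusted across the collection and the table is
    sorted by p.  The universe defaults to the union of all collection
    genes; the query is intersected with the universe before testing.
    """
    if universe is None:
        universe = frozenset().union(*collection.values()) if collection else frozenset()
    universe = frozenset(g.upper() for g in universe)
    query_set = frozenset(g.upper() for g in query) & universe
    if not universe or not query_set:
        raise ValueError("empty universe or query after harmonization")
    rows = []
    for name, genes in collection.items():
        genes_in_universe = genes & universe
        overlap = query_set & genes_in_universe
        # Upper tail P(X >= k): survival function at k-1.
        p = float(
            hypergeom.sf(
                len(overlap) - 1, len(universe), len(genes_in_universe), len(query_set)
            )
        )
        rows.append(
            {
                "pathway": name,
                "size": len(genes_in_universe),
                "overlap": len(overlap),
                "genes": ",".join(sorted(overlap)),
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table)
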