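"""Term enrichment (Fisher / EASE), cluster scores and interaction hubs.

Enrichment follows the DAVID conventions: the 2x2 table compares foreground
genes carrying a term against an annotated background, the p-value is the
one-tailed Fisher exact tail and, by default, the conservative EASE variant
in which the foreground hit count is decremented by one before taking the
tail.  Fold enrichment is (count / list total) / (pop hits / pop total).
Multiple testing is controlled with Benjamini-Hochberg over all tested
terms.  Cluster enrichment scores are the negative log10 of the geometric
mean of a term group's p-values.  Hub analysis counts the degree of each
node in an undirected interaction edge list (self-loops ignored, duplicate
edges counted once); a node is a hub when its degree exceeds the threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    count: int            # foreground genes with the term
    list_total: int       # foreground genes with any annotation
    pop_hits: int         # background genes with the term
    pop_total: int        # background genes with any annotation
    percent: float        # 100 * count / foreground size
    fold_enrichment: float
    p_value: float
    adjusted_p: float
    genes: list[str]


@dataclass(frozen=True)
class DegreeRow:
    node: str
    degree: int
    is_hub: bool


def fold_enrichment(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """(count / list_total) / (pop_hits / pop_total)."""
    if min(count, list_total, pop_hits, pop_total) < 0:
        raise ValueError("counts must be non-negative")
    if pop_hits == 0 or list_total == 0 or pop_total == 0:
        raise ValueError("zero denominator in fold enrichment")
    return (count / list_total) / (pop_hits / pop_total)


def fisher_tail(count: int, list_total: int, pop_hits: int, pop_total: int, ease: bool = True) -> float:
    """One-tailed Fisher exact p for enrichment; EASE decrements the count by 1.

    With X ~ Hypergeometric(pop_total, pop_hits, list_total), the plain tail
    is P(X >= count) and the EASE score is P(X >= count - 1).
    """
    k = count - 1 if ease else count
    # stats.hypergeom.sf(k-1, M, n, N) = P(X >= k)
    return float(min(1.0, stats.hypergeom.sf(k - 1, pop_total, pop_hits, list_total)))


def term_enrichment(
    fg_genes: Iterable[str],
    annotations: Mapping[str, set[str] | Sequence[str]],
    background_genes: Iterable[str] | None = None,
    ease: bool = True,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Enrichment of every annotation term in the foreground gene set.

    The background defaults to all genes appearing in the annotation table.
    Gene symbols are upper-cased before matching; foreground genes absent
    from the background are excluded with a warning.  Term-level p filtering
    is left to the caller.
    """
    terms = {t: {str(g).upper() for g in gs} for t, gs in annotations.items()}
    annotated = set().union(*terms.values()) if terms else set()
    bg = (
        {str(g).upper() for g in background_genes}
        if background_genes is not None
        else set(annotated)
    )
    fg = {str(g).upper() for g in fg_genes}
    missing = fg - bg
    if missing:
        log.warning("%d foreground genes absent from background; excluded", len(missing))
        fg &= bg

    fg_annotated = fg & annotated
    bg_annotated = bg & annotated
    list_total = len(fg_annotated)
    pop_total = len(bg_annotated)

    rows: list[EnrichmentRow] = []
    for term, genes in sorted(terms.items()):
        hit_genes = sorted(fg_annotated & genes)
        count = len(hit_genes)
        pop_hits = len(bg_annotated & genes)
        if count == 0 or pop_hits == 0:
            continue
        rows.append(
            EnrichmentRow(
                term_id=term,
                term_name=(term_names or {}).get(term, term),
                count=count,
                list_total=list_total,
                pop_hits=pop_hits,
                pop_total=pop_total,
                percent=100.0 * count / len(fg) if fg else 0.0,
                fold_enrichment=fold_enrichment(count, list_total, pop_hits, pop_total),
                p_value=fisher_tail(count, list_total, pop_hits, pop_total, ease=ease),
                adjusted_p=math.nan,
                genes=hit_genes,
            )
        )
    if rows:
        adj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        for r, a in zip(rows, adj):
            r.adjusted_p = float(max(a, r.p_value))
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def cluster_score(p_values_or_rows: Sequence[float] | Sequence[EnrichmentRow]) -> float:
    """-log10 of the geometric mean of a term group's p-values.

    A group qualifies as an enriched functional cluster above a score
    threshold (1.5 in the source study).  Zero p-values are clamped to the
    smallest positive float and flagged in the log.
    """
    if len(p_values_or_rows) == 0:
        raise ValueError("empty term group")
    ps = [
        r.p_value if isinstance(r, EnrichmentRow) else float(r)
        for r in p_values_or_rows
    ]
    tiny = 5e-324
    if any(p == 0.0 for p in ps):
        log.warning("zero p-value clamped to %.3g in cluster score", tiny)
    return -sum(math.log10(max(p, tiny)) for p in ps) / len(ps)


def degree_analysis(
    edges: Iterable[tuple[str, str]], hub_threshold: int = 7
) -> list[DegreeRow]:
    """Node degrees of an undirected edge list; hubs have degree > threshold."""
    unique: set[frozenset[str]] = set()
    for a, b in edges:
        if a == b:
            continue
        unique.add(frozenset((a, b)))
    degree: dict[str, int] = {}
    for edge in unique:
        for node in edge:
            degree[node] = degree.get(node, 0) + 1
    return [
        DegreeRow(node=n, degree=d, is_hub=d > hub_threshold)
        for n, d in sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def read_annotation_table(path) -> dict[str, set[str]]:
    """Two-column TSV ``term_id<TAB>gene`` -> term -> gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(term, set()).add(gene.upper())
    return out


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column TSV interaction edge list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    return list(zip(df["a"], df["b"]))


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Rows as a DAVID-style flat table."""
    return pd.DataFrame(
        {
            "term": [r.term_id for r in rows],
            "name": [r.term_name for r in rows],
            "count": [r.count for r in rows],
            "percent": [r.percent for r in rows],
            "p_value": [r.p_value for r in rows],
            "genes": [",".join(r.genes) for r in rows],
            "list_total": [r.list_total for r in rows],
            "pop_hits": [r.pop_hits for r in rows],
            "pop_total": [r.pop_total for r in rows],
            "fold_enrichment": [r.fold_enrichment for r in rows],
            "benjamini": [r.adjusted_p for r in rows],
        }
    )
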