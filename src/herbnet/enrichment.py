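"""Pathway over-representation analysis and table consolidation.

For a query gene list (the targets of one component or one phenotype's
routes) and a pathway gene set of size ``m`` inside a universe of ``N``
genes, the probability of seeing ``k`` or more overlapping genes in a
query of size ``q`` under random draws is the upper hypergeometric tail —
the one-sided Fisher exact p-value.  Only pathways with at least one
overlapping gene are reported.

Consolidation merges the per-component/per-phenotype tables the way a
spreadsheet sort-and-dedup would: rows ordered by overlap count
(descending), then p-value (most significant first), then name, keeping
the first occurrence of each pathway name.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace

from scipy.stats import hypergeom

from .errors import ValidationError
from .genesets import PathwayCollection
from .graph import normalize_gene_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    """One pathway's overlap with one query list."""

    pathway: str
    source: str  # component or phenotype the query came from
    overlap_genes: tuple[str, ...]
    k: int  # overlap count
    q: int  # query size (within universe)
    m: int  # pathway set size
    n_universe: int
    p: float
    p_adjusted: float | None = None

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p) if self.p > 0 else math.inf


def fisher_enrichment(
    query_genes: Iterable[str],
    collection: PathwayCollection,
    universe: Iterable[str] | None = None,
    source: str = "",
) -> list[EnrichmentRow]:
    """One-sided (over-representation) Fisher test per pathway.

    ``universe`` defaults to the union of the collection's gene sets.
    Query genes outside the universe are dropped with a warning; pathways
    with zero overlap are omitted.  p = P(X >= k) for X hypergeometric
    with population N, successes m, draws q.
    """
    uni = frozenset(
        normalize_gene_symbol(x) for x in universe
    ) if universe is not None else collection.universe()
    query = {normalize_gene_symbol(x) for x in query_genes}
    dropped = query - uni
    if dropped:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s",
            len(dropped), ", ".join(sorted(dropped)),
        )
    query &= uni
    if not query:
        raise ValidationError("query is empty after restricting to the universe")
    n_uni, q = len(uni), len(query)
    rows: list[EnrichmentRow] = []
    for name, genes in collection.items():
        members = genes & uni
        overlap = sorted(query & members)
        k, m = len(overlap), len(members)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, n_uni, m, q))
        rows.append(EnrichmentRow(name, source, tuple(overlap), k, q, m, n_uni, min(p, 1.0)))
    return rows


def consolidate(rows: Iterable[EnrichmentRow]) -> list[EnrichmentRow]:
    """Merge rows from several sources into one deduplicated ranking.

    Sort key: overlap count descending, p ascending, pathway name
    ascending; the first row per pathway name survives.
    """
    ordered = sorted(rows, key=lambda r: (-r.k, r.p, r.pathway, r.source))
    seen: set[str] = set()
    out: list[EnrichmentRow] = []
    for r in ordered:
        if r.pathway not in seen:
            seen.add(r.pathway)
            out.append(r)
    return out


def top_k(rows: Sequence[EnrichmentRow], k: int = 100) -> list[EnrichmentRow]:
    """First ``min(k, len)`` rows, order preserved."""
    if k < 1:
        raise ValidationError("top_k needs k >= 1")
    return list(rows[:k])


def benjamini_hochberg(rows: Sequence[EnrichmentRow]) -> list[EnrichmentRow]:
    """Attach Benjamini–Hochberg adjusted p-values (optional correction)."""
    if not rows:
        return []
    from statsmodels.stats.multitest import multipletests

    _, p_adj, _, _ = multipletests([r.p for r in rows], method="fdr_bh")
    return [replace(r, p_adjusted=float(pa)) for r, pa in zip(rows, p_adj)]
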