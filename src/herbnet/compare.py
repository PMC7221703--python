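"""Cross-phenotype pathway comparison and sub-network construction.

Given per-phenotype ranked pathway lists (from enrichment consolidation),
the pathways acting on *all* phenotypes are their set intersection — the
spreadsheet COUNTIF-equals-four filter done properly.  Comparing two herbs
(e.g., a processed and an unprocessed preparation), the pathways exclusive
to herb A are the set difference of the two shared sets.

From a pathway membership map restricted to a target set we rebuild the
bipartite target–pathway (T-P) network; adding component→target edges
extends it to the component–target–pathway (C-T-P) network.  Degree
ranking over one layer surfaces the hub targets/pathways.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import ValidationError
from .graph import LayeredGraph, LayerTag, normalize_gene_symbol


def _canon(name: str) -> str:
    """Exact-string pathway matching modulo whitespace and case."""
    return " ".join(name.split()).casefold()


@dataclass
class ComparisonResult:
    shared_a: set[str]
    shared_b: set[str]
    exclusive_a: set[str]
    exclusive_b: set[str]
    totals: dict[str, int] = field(default_factory=dict)


def shared_pathways(profile: Mapping[str, Iterable[str]]) -> set[str]:
    """Pathways present in every phenotype's list (set intersection).

    ``profile`` maps phenotype label → pathway names.  Names are matched
    after trimming and case-folding; the spelling from the first
    phenotype's list is returned.
    """
    if not profile:
        raise ValidationError("profile must contain at least one phenotype")
    iters = [{_canon(p): p for p in paths} for paths in profile.values()]
    common = set(iters[0])
    for d in iters[1:]:
        common &= set(d)
    return {iters[0][c] for c in common}


def exclusive_pathways(shared_a: Iterable[str], shared_b: Iterable[str]) -> set[str]:
    """Pathways in A's shared set absent from B's (A \\ B, canonicalized)."""
    b = {_canon(p) for p in shared_b}
    return {p for p in shared_a if _canon(p) not in b}


def compare_herbs(
    profile_a: Mapping[str, Iterable[str]], profile_b: Mapping[str, Iterable[str]]
) -> ComparisonResult:
    sa, sb = shared_pathways(profile_a), shared_pathways(profile_b)
    return ComparisonResult(
        shared_a=sa,
        shared_b=sb,
        exclusive_a=exclusive_pathways(sa, sb),
        exclusive_b=exclusive_pathways(sb, sa),
        totals={
            "herb_a_shared": len(sa),
            "herb_b_shared": len(sb),
            "herb_a_exclusive": len(sa) - len(sa & sb),
            "herb_b_exclusive": len(sb) - len(sa & sb),
        },
    )


def build_tp_network(
    memberships: Mapping[str, Iterable[str]], targets: Iterable[str]
) -> LayeredGraph:
    """Bipartite target–pathway graph restricted to a target set.

    An edge (t, p) exists iff gene ``t`` belongs to pathway ``p``'s list
    and to ``targets``.  Pathways left without members are dropped (no
    isolated pathway nodes).
    """
    if not memberships:
        raise ValidationError("pathway membership map is empty")
    tset = {normalize_gene_symbol(t) for t in targets}
    g = LayeredGraph()
    for pathway, genes in memberships.items():
        members = sorted({normalize_gene_symbol(x) for x in genes} & tset)
        if not members:
            continue
        p = g.add_node(LayerTag.PATHWAY, pathway)
        for t in members:
            g.add_edge(g.add_node(LayerTag.TARGET, t), p)
    return g


def build_ctp_network(
    component_targets: Mapping[str, Iterable[str]], tp: LayeredGraph
) -> LayeredGraph:
    """Union of component→target edges with an existing T-P network."""
    g = LayeredGraph()
    for nid in tp.nodes:
        g.add_node(tp.layer_of(nid), tp.label_of(nid))
    for s, t in tp.edges:
        g.add_edge(s, t)
    for comp, genes in component_targets.items():
        c = g.add_node(LayerTag.COMPONENT, comp)
        for gene in sorted({normalize_gene_symbol(x) for x in genes}):
            g.add_edge(c, g.add_node(LayerTag.TARGET, gene))
    return g


def degree_ranking(
    g: LayeredGraph, layer: LayerTag, top: int | None = 10
) -> list[tuple[str, int]]:
    """Nodes of one layer as (label, degree), degree-descending.

    Ties break lexicographically by label; ``top=None`` returns all.
    """
    nodes = g.nodes_in_layer(layer)
    if not nodes:
        raise ValidationError(f"graph has no {layer.value} nodes")
    ranked = sorted(((g.label_of(n), g.degree(n)) for n in nodes), key=lambda x: (-x[1], x[0]))
    return ranked if top is None else ranked[:top]
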