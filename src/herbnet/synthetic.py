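"""Built-in red-ginseng fixture and synthetic knowledge-graph generator.

Two data sources feed the pipeline's tests and examples:

* **The red-ginseng fixture** — the published component→gene and
  pathway→gene lists for the five red-ginseng signature components
  (ginsenosides Rg1, Rb1, Re, notoginsenoside R1, and salicylate), nine
  signaling pathways, and the four clinical phenotypes of interest.  The
  two gene-list families are stored verbatim and independently: the union
  of the component lists is 37 symbols while the union of the pathway
  lists is 35 (FOS and JUN appear only on the component side); we do not
  reconcile them.  Per-phenotype target lists are not published beyond a
  top-10 table, so the fixture wires every target to every phenotype
  uniformly and keeps the top-10 table as a separate expected-ranking
  record rather than as edges.

* **A seeded generator** emulating the structure of the herb-compound
  knowledge bases the published analysis drew on (one herb, tens of
  components, a component→target bipartite layer, pathway gene sets, and
  phenotype wiring), with a planted over-enriched pathway and a planted
  high-connectivity phenotype as recoverable ground truth.

Generator defaults mirror the fixture's scale (5 components, ~40 targets,
10 pathways) so property tests over many seeds run in seconds.  Pathway
gene sets are sampled from a decoy pool five times larger than the target
layer, which keeps the null overlap between a random pathway and the
component-hit query well below one gene, so the planted signal is the
kind of clear over-representation the method is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .genesets import PathwayCollection
from .graph import LayeredGraph, LayerTag

HERB_NAME = "red ginseng"

#: Signature components and their published associated genes.
COMPONENT_TARGETS: dict[str, tuple[str, ...]] = {
    "ginsenoside Rg1": (
        "AKT1", "APP", "BAD", "BCL2", "MAPK1", "MAPK3", "MAPK8", "MAPK9",
        "NFKBIA", "NGF", "PLCG1", "TNF",
    ),
    "ginsenoside Rb1": ("AKT1", "IL6", "TNF"),
    "ginsenoside Re": (
        "AKT1", "CASP3", "FAS", "FOS", "IFNG", "IL1B", "IL6", "IRAK1",
        "IRAK4", "MAPK1", "MAPK3", "MYL9", "MYLK", "NFKBIA", "NOS3",
        "OCLN", "PTGS2", "ROCK1", "TGFB1", "TJP1", "TNF",
    ),
    "notoginsenoside R1": (
        "AKT1", "BAD", "BCL2", "CASP3", "CASP8", "FAS", "FOS", "IFNG",
        "IL2", "IL4", "JUN", "MAPK1", "MAPK3", "MAPK9", "NFKBIA", "OCLN",
        "PIK3R1", "ROCK1", "TJP1", "TNF", "TNFRSF1A",
    ),
    "salicylate": (
        "AKT1", "EGF", "ICAM1", "IFNG", "IL4", "MAPK1", "MAPK3", "NFKBIA",
        "TGFB1", "VCAM1",
    ),
}

#: The nine red-ginseng-only signaling pathways with their published members.
PATHWAY_GENES: dict[str, tuple[str, ...]] = {
    "Vascular Endothelial Cell Activation by Growth Factors": (
        "PLCG1", "NFKBIA", "MAPK3", "MAPK1", "VCAM1", "EGF", "TGFB1",
        "AKT1", "ICAM1", "PTGS2", "NOS3",
    ),
    "Natural Killer Cell Activation through ITAM-Containing Receptors": (
        "FAS", "BAD", "BCL2", "PIK3R1", "AKT1", "CASP3", "TNF",
        "TNFRSF1A", "CASP8", "PLCG1",
    ),
    "Peripheral T-Cell Tolerance: Overview": (
        "FAS", "BAD", "BCL2", "PIK3R1", "AKT1", "CASP3", "TNF",
        "TNFRSF1A", "CASP8", "PLCG1",
    ),
    "T-Cell Receptor Signaling": (
        "MAPK9", "PLCG1", "NFKBIA", "IFNG", "IL4", "IL2", "MAPK3",
        "MAPK1", "AKT1",
    ),
    "Th1-Cell Differentiation": (
        "MAPK9", "PLCG1", "NFKBIA", "IFNG", "MAPK3", "MAPK1", "IRAK1",
        "IRAK4", "AKT1",
    ),
    "Vascular Endothelial Cell Permeability Activation": (
        "NFKBIA", "NOS3", "ROCK1", "MYL9", "TJP1", "MYLK", "OCLN",
        "AKT1", "PLCG1",
    ),
    "Th17-Cell Differentiation": (
        "PLCG1", "NFKBIA", "IL1B", "IL6", "IRAK1", "IRAK4", "TGFB1", "AKT1",
    ),
    "T-Cell Central Tolerance": ("PLCG1", "MAPK8", "AKT1", "BAD", "BCL2"),
    "GFs/TNF Ion Channels": ("PLCG1", "NGF", "APP", "TNF"),
}

PHENOTYPES: tuple[str, ...] = (
    "menopausal symptoms in women",
    "blood circulation",
    "hyperlipidemia",
    "diabetes mellitus",
)

#: Published per-phenotype top-10 target rankings (expected-output record,
#: not edges; their derivation needs the full association graph).
TOP10_TARGETS: dict[str, tuple[str, ...]] = {
    "menopausal symptoms in women": (
        "TNF", "AKT1", "FOS", "JUN", "MAPK1", "MAPK3", "NFKBIA", "CREB1",
        "IL6", "IRAK1",
    ),
    "blood circulation": (
        "MAPK1", "TNF", "MAPK3", "NFKBIA", "IL6", "AKT1", "FOS", "TGFB1",
        "ROCK1", "BCL2",
    ),
    "hyperlipidemia": ("PLCG1", "IRAK4", "MAPK9"),
    "diabetes mellitus": ("PLCG1", "IRAK4", "MAPK9"),
}


def build_red_ginseng_fixture() -> tuple[LayeredGraph, PathwayCollection]:
    """Assemble the packaged fixture graph and its pathway collection.

    The graph holds one herb node, the 5 components, the 37-target union
    of the component lists, the 9 pathways (edges per the published
    membership lists), and the 4 phenotypes wired to every target.
    """
    g = LayeredGraph()
    herb = g.add_node(LayerTag.HERB, HERB_NAME)
    for comp, genes in COMPONENT_TARGETS.items():
        c = g.add_node(LayerTag.COMPONENT, comp)
        g.add_edge(herb, c)
        for gene in genes:
            g.add_edge(c, g.add_node(LayerTag.TARGET, gene))
    for pathway, genes in PATHWAY_GENES.items():
        p = g.add_node(LayerTag.PATHWAY, pathway)
        for gene in genes:
            g.add_edge(g.add_node(LayerTag.TARGET, gene), p)
    targets = g.nodes_in_layer(LayerTag.TARGET)
    for phen in PHENOTYPES:
        ph = g.add_node(LayerTag.PHENOTYPE, phen)
        for t in targets:
            g.add_edge(t, ph)
    coll = PathwayCollection()
    for pathway, genes in PATHWAY_GENES.items():
        coll.add(pathway, genes)
    return g, coll


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorParams:
    """Knobs of the synthetic knowledge-graph generator.

    ``edge_prob`` is the independent probability that a component hits a
    target; ``planted_pathway_overlap`` query genes are forced into one
    pathway; ``planted_phenotype_targets`` component-hit targets are wired
    to one designated phenotype (the other phenotypes get the same number
    of edges, but to targets the components do not hit).
    """

    n_components: int = 5
    n_targets: int = 40
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (4, 8)
    edge_prob: float = 0.1
    planted_pathway_overlap: int = 5
    planted_phenotype_targets: int = 8
    decoy_pool_factor: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ParameterError(f"edge_prob must lie in [0, 1], got {self.edge_prob}")
        for name in ("n_components", "n_targets", "n_pathways", "decoy_pool_factor"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ParameterError(f"invalid pathway_size_range {self.pathway_size_range}")
        if self.planted_pathway_overlap < 0 or self.planted_phenotype_targets < 0:
            raise ParameterError("planted counts must be nonnegative")
        if self.planted_pathway_overlap > hi:
            raise ParameterError(
                f"planted_pathway_overlap={self.planted_pathway_overlap} exceeds the "
                f"maximum pathway size {hi}"
            )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    planted_pathway: str | None
    planted_phenotype: str | None
    query_genes: tuple[str, ...] = field(default_factory=tuple)


def generate_graph(
    params: GeneratorParams,
) -> tuple[LayeredGraph, PathwayCollection, GroundTruth]:
    """Sample a layered knowledge graph with planted signal.

    Deterministic for a fixed ``params.seed``.  Raises
    :class:`ParameterError` when the planted counts cannot be satisfied by
    the sampled component→target edges (e.g., the query is smaller than
    the requested planted overlap).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    width = len(str(params.n_targets * params.decoy_pool_factor))
    pool = [f"G{i + 1:0{width}d}" for i in range(params.n_targets * params.decoy_pool_factor)]
    target_genes = pool[: params.n_targets]

    g = LayeredGraph()
    herb = g.add_node(LayerTag.HERB, "synthetic herb")
    components = [f"component-{i + 1:02d}" for i in range(params.n_components)]
    for comp in components:
        g.add_edge(herb, g.add_node(LayerTag.COMPONENT, comp))
    for t in target_genes:
        g.add_node(LayerTag.TARGET, t)

    hits = rng.random((params.n_components, params.n_targets)) < params.edge_prob
    for i, comp in enumerate(components):
        c = g.add_node(LayerTag.COMPONENT, comp)
        for j in np.flatnonzero(hits[i]):
            g.add_edge(c, g.add_node(LayerTag.TARGET, target_genes[j]))
    query = sorted({target_genes[j] for j in np.flatnonzero(hits.any(axis=0))})

    # Pathway gene sets from the decoy pool; one pathway gets the plant.
    lo, hi = params.pathway_size_range
    coll = PathwayCollection()
    planted_pathway: str | None = None
    if params.planted_pathway_overlap > 0:
        if params.planted_pathway_overlap > len(query):
            raise ParameterError(
                f"planted_pathway_overlap={params.planted_pathway_overlap} exceeds the "
                f"{len(query)} component-associated genes available"
            )
        planted_idx = int(rng.integers(params.n_pathways))
    else:
        planted_idx = -1
    non_query_pool = [x for x in pool if x not in set(query)]
    for i in range(params.n_pathways):
        name = f"pathway-{i + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        if i == planted_idx:
            forced = list(rng.choice(query, size=params.planted_pathway_overlap, replace=False))
            fill = max(size - len(forced), 0)
            genes = forced + list(rng.choice(non_query_pool, size=fill, replace=False))
            planted_pathway = name
        else:
            genes = list(rng.choice(pool, size=size, replace=False))
        coll.add(name, genes)
        p = g.add_node(LayerTag.PATHWAY, name)
        for gene in genes:
            if gene in set(target_genes):
                g.add_edge(g.add_node(LayerTag.TARGET, gene), p)

    # Phenotypes: the planted one is wired to component-hit targets, the
    # decoys to targets the components do not hit.
    planted_phenotype: str | None = None
    if params.planted_phenotype_targets > 0:
        if params.planted_phenotype_targets > len(query):
            raise ParameterError(
                f"planted_phenotype_targets={params.planted_phenotype_targets} exceeds the "
                f"{len(query)} component-associated targets available"
            )
        planted_ph_idx = int(rng.integers(len(PHENOTYPES)))
    else:
        planted_ph_idx = -1
    non_query_targets = [t for t in target_genes if t not in set(query)]
    for i, phen in enumerate(PHENOTYPES):
        ph = g.add_node(LayerTag.PHENOTYPE, phen)
        if params.planted_phenotype_targets == 0:
            continue
        if i == planted_ph_idx:
            wired = rng.choice(query, size=params.planted_phenotype_targets, replace=False)
            planted_phenotype = phen
        else:
            n_wire = min(params.planted_phenotype_targets, len(non_query_targets))
            wired = rng.choice(non_query_targets, size=n_wire, replace=False)
        for t in wired:
            g.add_edge(g.add_node(LayerTag.TARGET, str(t)), ph)

    return g, coll, GroundTruth(planted_pathway, planted_phenotype, tuple(query))
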