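"""Route enumeration and path-frequency scoring.

A route follows the template component → target → entity, where the
terminal entity is a biological process, pathway, or phenotype node.  For
a queried phenotype, a route counts when its terminal is that phenotype
itself, or when the terminal is a pathway/bioprocess and the route's
target also carries an edge to the queried phenotype (the target is
phenotype-associated, so the processes it regulates are routes toward that
phenotype).  An optional four-layer template inserts a pathway between the
target and the phenotype.

Each route is scored by the mean, over its nodes, of the fraction of the
corpus's routes containing that node:

    score(r) = (1/n) * sum_i count(routes containing node_i) / count(routes)

so a route through frequently traversed nodes scores near 1 and a route
through idiosyncratic nodes scores near 1/count.  Frequencies are counted
within one phenotype's route corpus.  Ranking keeps, per terminal entity,
only the best-scoring route, then sorts by score (descending; ties broken
by terminal label).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from .errors import ValidationError
from .graph import LayeredGraph, LayerTag, node_id

_TERMINAL_LAYERS = (LayerTag.BIOPROCESS, LayerTag.PATHWAY, LayerTag.PHENOTYPE)


@dataclass(frozen=True, order=True)
class Route:
    """An ordered component→target→…→entity walk through the graph."""

    nodes: tuple[str, ...]

    @property
    def component(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[1]

    @property
    def terminal(self) -> str:
        return self.nodes[-1]

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class PathScoreTable:
    """Scored route corpus: routes, their scores, and the node counts."""

    routes: list[Route]
    scores: list[float]
    frequencies: Counter
    total: int

    def rows(self) -> list[tuple[Route, float]]:
        return list(zip(self.routes, self.scores))


def enumerate_routes(
    g: LayeredGraph, phenotype: str, layers: int = 3
) -> list[Route]:
    """List every route relevant to ``phenotype``, lexicographically ordered.

    ``phenotype`` is the phenotype node's label.  ``layers=3`` walks
    component→target→entity; ``layers=4`` walks
    component→target→pathway→phenotype.
    """
    ph = node_id(LayerTag.PHENOTYPE, phenotype)
    if ph not in g:
        raise ValidationError(f"unknown phenotype {phenotype!r}")
    if layers not in (3, 4):
        raise ValidationError("route template must have 3 or 4 layers")
    routes: list[Route] = []
    for comp in g.nodes_in_layer(LayerTag.COMPONENT):
        for tgt in g.successors(comp):
            if g.layer_of(tgt) is not LayerTag.TARGET:
                continue
            target_hits_phenotype = g.has_edge(tgt, ph)
            for ent in g.successors(tgt):
                ent_layer = g.layer_of(ent)
                if layers == 3:
                    if ent_layer not in _TERMINAL_LAYERS:
                        continue
                    if ent == ph or (
                        ent_layer in (LayerTag.PATHWAY, LayerTag.BIOPROCESS)
                        and target_hits_phenotype
                    ):
                        routes.append(Route((comp, tgt, ent)))
                else:
                    if ent_layer is not LayerTag.PATHWAY:
                        continue
                    if g.has_edge(ent, ph):
                        routes.append(Route((comp, tgt, ent, ph)))
    return sorted(routes)


def node_frequencies(routes: Sequence[Route]) -> tuple[Counter, int]:
    """Per-node route-membership counts and the corpus size."""
    if not routes:
        raise ValidationError("cannot compute frequencies of an empty route corpus")
    freq: Counter = Counter()
    for r in routes:
        freq.update(set(r.nodes))
    return freq, len(routes)


def path_score(route: Route, freq: Mapping[str, int], total: int) -> float:
    """Mean node frequency of the route, relative to the corpus size."""
    if total < 1:
        raise ValidationError("corpus must contain at least one route")
    missing = [n for n in route.nodes if n not in freq]
    if missing:
        raise ValidationError(f"route node {missing[0]!r} missing from frequency map")
    return sum(freq[n] for n in route.nodes) / total / route.n


def score_routes(routes: Sequence[Route]) -> PathScoreTable:
    freq, total = node_frequencies(routes)
    scores = [path_score(r, freq, total) for r in routes]
    return PathScoreTable(list(routes), scores, freq, total)


def rank_routes(
    table: PathScoreTable, label_of: Mapping[str, str] | None = None
) -> list[tuple[Route, float]]:
    """Deduplicate by terminal entity (best score wins) and sort.

    Per terminal, the highest-scoring route is retained (ties broken by
    the lexicographically smallest node sequence); the result is sorted by
    score descending, ties by terminal label ascending.
    """
    labels = label_of or {}
    best: dict[str, tuple[Route, float]] = {}
    for route, score in sorted(table.rows(), key=lambda rs: (-rs[1], rs[0].nodes)):
        best.setdefault(route.terminal, (route, score))
    return sorted(
        best.values(), key=lambda rs: (-rs[1], labels.get(rs[0].terminal, rs[0].terminal))
    )


def route_target_genes(routes: Iterable[Route], g: LayeredGraph) -> set[str]:
    """Gene symbols of the targets traversed by a route corpus."""
    return {g.label_of(r.target) for r in routes}
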