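"""Layered knowledge-graph model and interchange I/O.

The pipeline's central container is a directed graph whose nodes live in
one of six layers: herb, component (a chemical constituent of the herb),
target (a human gene/protein), pathway, bioprocess, and phenotype.  Edges
are only allowed between adjacent layers (herb→component, component→target,
target→pathway/bioprocess/phenotype, pathway→phenotype); the direction
records provenance, but connectivity-based quantities (degree, random-walk
transition weights) treat edges as undirected, because a "connection count"
is what degree means in this setting.

Node identifiers embed the layer (``"PATHWAY:Th17-Cell Differentiation"``)
so that, e.g., a gene and a pathway sharing a label never collide.
"""

from __future__ import annotations

import csv
import enum
from collections.abc import Iterable
from pathlib import Path

import networkx as nx

from .errors import ParseError, ValidationError


class LayerTag(enum.Enum):
    """Closed enumeration of the network layers."""

    HERB = "HERB"
    COMPONENT = "COMPONENT"
    TARGET = "TARGET"
    PATHWAY = "PATHWAY"
    BIOPROCESS = "BIOPROCESS"
    PHENOTYPE = "PHENOTYPE"


#: Layer pairs an edge may connect (source layer, target layer).
ALLOWED_PAIRS: frozenset[tuple[LayerTag, LayerTag]] = frozenset(
    {
        (LayerTag.HERB, LayerTag.COMPONENT),
        (LayerTag.COMPONENT, LayerTag.TARGET),
        (LayerTag.TARGET, LayerTag.PATHWAY),
        (LayerTag.TARGET, LayerTag.BIOPROCESS),
        (LayerTag.TARGET, LayerTag.PHENOTYPE),
        (LayerTag.PATHWAY, LayerTag.PHENOTYPE),
    }
)

# The literature mixes protein-style and symbol-style notation; map the
# common variants onto the HGNC symbol before use.
_SYMBOL_ALIASES = {
    "TNF-A": "TNF",
    "TNF-ALPHA": "TNF",
    "TNFALPHA": "TNF",
    "TNF-Α": "TNF",  # Greek capital alpha
    "TNFΑ": "TNF",
    "TGF-B1": "TGFB1",
    "TGF-BETA1": "TGFB1",
}


def normalize_gene_symbol(symbol: str) -> str:
    """Uppercase, trim, and canonicalize a gene/protein identifier.

    ``"TNF-α"`` → ``"TNF"``; plain HGNC symbols pass through unchanged.
    """
    s = symbol.strip().upper().replace("α", "Α")
    return _SYMBOL_ALIASES.get(s, s)


def node_id(layer: LayerTag, label: str) -> str:
    return f"{layer.value}:{label}"


def split_node_id(nid: str) -> tuple[LayerTag, str]:
    prefix, _, label = nid.partition(":")
    try:
        return LayerTag(prefix), label
    except ValueError:
        raise ValidationError(f"node id {nid!r} does not start with a known layer tag") from None


class LayeredGraph:
    """Simple directed multilayer graph with layer-pair validation.

    Nodes are keyed by ``"LAYER:label"`` ids.  Self-loops are impossible
    (an edge always crosses layers) and duplicate edges collapse.
    """

    def __init__(self) -> None:
        self._layers: dict[str, LayerTag] = {}
        self._labels: dict[str, str] = {}
        self._edges: set[tuple[str, str]] = set()
        self._adj: dict[str, set[str]] = {}

    # -- construction -------------------------------------------------

    def add_node(self, layer: LayerTag, label: str) -> str:
        if layer is LayerTag.TARGET:
            label = normalize_gene_symbol(label)
        nid = node_id(layer, label)
        if nid not in self._layers:
            self._layers[nid] = layer
            self._labels[nid] = label
            self._adj[nid] = set()
        return nid

    def add_edge(self, source: str, target: str) -> None:
        for nid in (source, target):
            if nid not in self._layers:
                raise ValidationError(f"edge endpoint {nid!r} is not in the node set")
        pair = (self._layers[source], self._layers[target])
        if pair not in ALLOWED_PAIRS:
            raise ValidationError(
                f"edge layer pair {pair[0].value}->{pair[1].value} is not allowed"
            )
        self._edges.add((source, target))
        self._adj[source].add(target)
        self._adj[target].add(source)

    # -- inspection ----------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node ids in sorted order (deterministic iteration)."""
        return sorted(self._layers)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._layers)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, nid: str) -> bool:
        return nid in self._layers

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self._edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LayeredGraph):
            return NotImplemented
        return self._layers == other._layers and self._edges == other._edges

    def layer_of(self, nid: str) -> LayerTag:
        self._require(nid)
        return self._layers[nid]

    def label_of(self, nid: str) -> str:
        self._require(nid)
        return self._labels[nid]

    def nodes_in_layer(self, layer: LayerTag) -> list[str]:
        return sorted(n for n, lt in self._layers.items() if lt is layer)

    def neighbors(self, nid: str) -> list[str]:
        """Direction-blind neighbourhood, sorted."""
        self._require(nid)
        return sorted(self._adj[nid])

    def successors(self, nid: str) -> list[str]:
        self._require(nid)
        return sorted(t for s, t in self._edges if s == nid)

    def degree(self, nid: str) -> int:
        """Count of incident edges regardless of direction."""
        self._require(nid)
        return len(self._adj[nid])

    def degree_table(self) -> dict[str, int]:
        return {nid: len(adj) for nid, adj in self._adj.items()}

    def _require(self, nid: str) -> None:
        if nid not in self._layers:
            raise ValidationError(f"unknown node {nid!r}")

    # -- derived graphs ------------------------------------------------

    def subgraph(self, layers: Iterable[LayerTag]) -> "LayeredGraph":
        """Induced subgraph on the nodes whose layer is in ``layers``."""
        keep = set(layers)
        if not keep:
            raise ValidationError("subgraph requires at least one layer")
        out = LayeredGraph()
        for nid, layer in self._layers.items():
            if layer in keep:
                out.add_node(layer, self._labels[nid])
        for s, t in self._edges:
            if self._layers[s] in keep and self._layers[t] in keep:
                out.add_edge(s, t)
        return out

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid in self.nodes:
            g.add_node(nid, layer=self._layers[nid].value, label=self._labels[nid])
        g.add_edges_from(sorted(self._edges))
        return g


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_HEADER_WORDS = {"source", "target", "from", "to", "src", "dst"}


def load_edges(
    path: str | Path,
    layer_map: tuple[LayerTag, LayerTag],
    graph: LayeredGraph | None = None,
) -> LayeredGraph:
    """Read a two-column TSV edge list into a layered graph.

    ``layer_map`` assigns a layer to the first and second column.  Lines
    starting with ``#`` are comments; a leading ``source<TAB>target``-style
    header row is skipped.  Duplicate rows collapse.  When ``graph`` is
    given, edges are merged into it (used to assemble a multi-family graph
    from several files).
    """
    src_layer, dst_layer = layer_map
    if (src_layer, dst_layer) not in ALLOWED_PAIRS:
        raise ValidationError(
            f"edge layer pair {src_layer.value}->{dst_layer.value} is not allowed"
        )
    g = graph if graph is not None else LayeredGraph()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        first_data_row = True
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            cells = [c.strip() for c in row]
            if first_data_row and cells[0].lower() in _HEADER_WORDS:
                first_data_row = False
                continue
            first_data_row = False
            if len(cells) < 2 or not cells[0] or not cells[1]:
                raise ParseError(
                    f"expected two tab-separated columns, got {row!r}", line=lineno
                )
            s = g.add_node(src_layer, cells[0])
            t = g.add_node(dst_layer, cells[1])
            g.add_edge(s, t)
    return g


def write_edges(g: LayeredGraph, pair: tuple[LayerTag, LayerTag], path: str | Path) -> None:
    """Write the edges of one layer family as a two-column TSV."""
    rows = sorted(
        (g.label_of(s), g.label_of(t))
        for s, t in g.edges
        if g.layer_of(s) is pair[0] and g.layer_of(t) is pair[1]
    )
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in rows:
            fh.write(f"{s}\t{t}\n")


def export_network(g: LayeredGraph, fmt: str, path: str | Path) -> None:
    """Write the graph as SIF or GraphML.

    SIF lines are ``source<TAB>links<TAB>target``; isolated nodes appear as
    a bare id on their own line.  GraphML stores layer and label as node
    attributes.  Both formats round-trip through the matching reader.
    """
    fmt = fmt.lower()
    if fmt == "sif":
        connected = {n for e in g.edges for n in e}
        with open(path, "w", encoding="utf-8") as fh:
            for s, t in sorted(g.edges):
                fh.write(f"{s}\tlinks\t{t}\n")
            for nid in g.nodes:
                if nid not in connected:
                    fh.write(f"{nid}\n")
    elif fmt == "graphml":
        nx.write_graphml(g.to_networkx(), str(path))
    else:
        raise ValidationError(f"unknown export format {fmt!r} (expected 'sif' or 'graphml')")


def read_sif(path: str | Path) -> LayeredGraph:
    g = LayeredGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) == 1:
                g.add_node(*split_node_id(cells[0]))
            elif len(cells) == 3:
                s = g.add_node(*split_node_id(cells[0]))
                t = g.add_node(*split_node_id(cells[2]))
                g.add_edge(s, t)
            else:
                raise ParseError(f"SIF line must have 1 or 3 fields, got {len(cells)}", line=lineno)
    return g


def read_graphml(path: str | Path) -> LayeredGraph:
    nxg = nx.read_graphml(str(path))
    g = LayeredGraph()
    for nid, data in nxg.nodes(data=True):
        g.add_node(LayerTag(data["layer"]), data["label"])
    for s, t in nxg.edges():
        g.add_edge(s, t)
    return g
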