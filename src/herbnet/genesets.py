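"""Pathway gene-set collections and GMT I/O.

GMT is the tab-delimited MSigDB dialect: one set per line, fields
``name<TAB>description<TAB>gene1<TAB>gene2...``.  Gene symbols are
uppercased and trimmed on load so that membership tests against graph
target labels are exact-string.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError
from .graph import normalize_gene_symbol


@dataclass
class PathwayCollection:
    """Named gene sets plus the gene universe they are drawn from.

    The default universe is the union of the member sets; enrichment can
    override it with, e.g., the graph's target layer.
    """

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ParseError(f"duplicate pathway name {name!r}")
        genes = frozenset(normalize_gene_symbol(g) for g in genes if g.strip())
        if not genes:
            raise ParseError(f"pathway {name!r} has an empty gene set")
        self.sets[name] = genes
        self.descriptions[name] = description

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def universe(self) -> frozenset[str]:
        u: frozenset[str] = frozenset()
        for s in self.sets.values():
            u |= s
        return u

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def load_gene_sets(path: str | Path) -> PathwayCollection:
    """Parse a GMT file into a :class:`PathwayCollection`.

    Raises :class:`ParseError` (with the line number) on a short line, a
    duplicate set name, or a set that is empty after trimming.
    """
    coll = PathwayCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and at least one gene", line=lineno
                )
            name, desc, genes = fields[0].strip(), fields[1].strip(), fields[2:]
            try:
                coll.add(name, genes, desc)
            except ParseError as exc:
                raise ParseError(str(exc), line=lineno) from None
    return coll


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
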