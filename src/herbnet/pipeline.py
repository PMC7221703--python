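"""End-to-end pipeline: inputs → RWR → routes → enrichment → comparison.

The stages mirror the inference chain the package implements: load (or
generate) the layered knowledge graph, score phenotypes by random walk
with restart from the component-associated targets, enumerate and rank
component→target→entity routes per phenotype, run per-component pathway
over-representation on each phenotype's route targets and consolidate,
intersect the per-phenotype pathway profiles, and rebuild/export the
target–pathway and component–target–pathway networks.  Every output is a
sorted plain-text table, so a fixed seed yields byte-identical runs; a
manifest records the configuration, package versions, and headline counts.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
import pydantic
import yaml

from . import __version__
from .compare import build_ctp_network, build_tp_network, shared_pathways
from .enrichment import EnrichmentRow, benjamini_hochberg, consolidate, fisher_enrichment, top_k
from .errors import ConfigError, HerbnetError
from .genesets import PathwayCollection, load_gene_sets, write_gmt
from .graph import LayeredGraph, LayerTag, export_network, load_edges, write_edges
from .paths import enumerate_routes, rank_routes, score_routes
from .randomwalk import phenotype_scores
from .synthetic import GeneratorParams, build_red_ginseng_fixture, generate_graph

logger = logging.getLogger(__name__)

_EDGE_FAMILIES: tuple[tuple[LayerTag, LayerTag], ...] = (
    (LayerTag.HERB, LayerTag.COMPONENT),
    (LayerTag.COMPONENT, LayerTag.TARGET),
    (LayerTag.TARGET, LayerTag.PATHWAY),
    (LayerTag.TARGET, LayerTag.BIOPROCESS),
    (LayerTag.TARGET, LayerTag.PHENOTYPE),
    (LayerTag.PATHWAY, LayerTag.PHENOTYPE),
)


class _Model(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class EdgeFileConfig(_Model):
    path: str
    source_layer: str
    target_layer: str

    def layer_pair(self) -> tuple[LayerTag, LayerTag]:
        try:
            return LayerTag(self.source_layer.upper()), LayerTag(self.target_layer.upper())
        except ValueError as exc:
            raise ConfigError(f"unknown layer tag in edge file config: {exc}") from None


class RWConfig(_Model):
    alpha: float = 0.7
    threshold: float = 1e-6
    max_iter: int = 10_000


class EnrichmentConfig(_Model):
    top_k: int = 100
    correction: bool = False
    universe: Literal["gmt", "targets"] = "gmt"


class GeneratorConfig(_Model):
    n_components: int = 5
    n_targets: int = 40
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (4, 8)
    edge_prob: float = 0.1
    planted_pathway_overlap: int = 5
    planted_phenotype_targets: int = 8
    decoy_pool_factor: int = 5

    def to_params(self, seed: int) -> GeneratorParams:
        return GeneratorParams(seed=seed, **self.model_dump())


class PipelineConfig(_Model):
    """Validated configuration for one pipeline run."""

    fixture: bool = False
    edges: list[EdgeFileConfig] = []
    gmt: Optional[str] = None
    route_layers: int = 3
    rw: RWConfig = RWConfig()
    enrichment: EnrichmentConfig = EnrichmentConfig()
    generator: GeneratorConfig = GeneratorConfig()
    seed: int = 0
    outdir: str = "results"


def load_config(path: str | Path | None, overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Read a YAML config, apply CLI overrides, validate against the schema."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        cursor = data
        parts = key.split(".")
        for part in parts[:-1]:
            cursor = cursor.setdefault(part, {})
        cursor[parts[-1]] = value
    try:
        return PipelineConfig.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ConfigError(str(exc)) from None


def load_inputs(cfg: PipelineConfig) -> tuple[LayeredGraph, PathwayCollection]:
    """Materialize the graph and pathway collection a config points at."""
    if cfg.fixture:
        return build_red_ginseng_fixture()
    if not cfg.edges:
        raise ConfigError("config needs either fixture: true or a nonempty edges list")
    if cfg.gmt is None:
        raise ConfigError("config needs a gmt path for pathway gene sets")
    g = LayeredGraph()
    for ef in cfg.edges:
        load_edges(ef.path, ef.layer_pair(), graph=g)
    return g, load_gene_sets(cfg.gmt)


def _slug(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", label).strip("_").lower()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "source": r.source,
                "overlap": ";".join(r.overlap_genes),
                "k": r.k,
                "q": r.q,
                "m": r.m,
                "N": r.n_universe,
                "p": r.p,
                "neg_log10_p": r.neg_log10_p,
                **({"p_adjusted": r.p_adjusted} if r.p_adjusted is not None else {}),
            }
            for r in rows
        ]
    )


def component_target_map(g: LayeredGraph) -> dict[str, list[str]]:
    """Component label → sorted target gene symbols, from the graph."""
    out: dict[str, list[str]] = {}
    for comp in g.nodes_in_layer(LayerTag.COMPONENT):
        genes = sorted(
            g.label_of(t) for t in g.successors(comp) if g.layer_of(t) is LayerTag.TARGET
        )
        out[g.label_of(comp)] = genes
    return out


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and write the result bundle under ``cfg.outdir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        g, coll = load_inputs(cfg)
        comp_targets = component_target_map(g)
        start_nodes = sorted({t for genes in comp_targets.values() for t in genes})
        start_ids = [f"{LayerTag.TARGET.value}:{t}" for t in start_nodes]
        universe = (
            coll.universe()
            if cfg.enrichment.universe == "gmt"
            else {g.label_of(t) for t in g.nodes_in_layer(LayerTag.TARGET)}
        )

        stage = "random_walk"
        logger.info("stage random_walk: %d start nodes", len(start_ids))
        scores = phenotype_scores(
            g, start_ids, alpha=cfg.rw.alpha, threshold=cfg.rw.threshold, max_iter=cfg.rw.max_iter
        )
        score_df = pd.DataFrame(
            [
                {
                    "node": nid,
                    "score": s.normalized,
                    "raw_score": s.raw,
                    "baseline": s.baseline,
                }
                for nid, s in sorted(scores.items())
            ]
        ).sort_values(["score", "node"], ascending=[False, True])
        _write_tsv(score_df, outdir / "phenotype_scores.tsv")

        stage = "routes"
        phenotypes = [g.label_of(p) for p in g.nodes_in_layer(LayerTag.PHENOTYPE)]
        profiles: dict[str, list[str]] = {}
        route_counts: dict[str, int] = {}
        labels = {nid: g.label_of(nid) for nid in g.nodes}
        for phen in phenotypes:
            routes = enumerate_routes(g, phen, layers=cfg.route_layers)
            route_counts[phen] = len(routes)
            if routes:
                ranked = rank_routes(score_routes(routes), label_of=labels)
                route_df = pd.DataFrame(
                    [
                        {
                            "component": g.label_of(r.component),
                            "target": g.label_of(r.target),
                            "terminal": g.label_of(r.terminal),
                            "score": s,
                        }
                        for r, s in ranked
                    ]
                )
            else:
                route_df = pd.DataFrame(columns=["component", "target", "terminal", "score"])
            _write_tsv(route_df, outdir / f"routes_{_slug(phen)}.tsv")

            stage = f"enrichment[{phen}]"
            route_targets = {g.label_of(r.target) for r in routes}
            rows: list[EnrichmentRow] = []
            for comp, genes in comp_targets.items():
                query = sorted(set(genes) & route_targets)
                if not query or not (set(query) & universe):
                    continue
                rows.extend(fisher_enrichment(query, coll, universe=universe, source=comp))
            merged = top_k(consolidate(rows), cfg.enrichment.top_k) if rows else []
            if cfg.enrichment.correction:
                merged = benjamini_hochberg(merged)
            _write_tsv(_enrichment_frame(merged), outdir / f"enrichment_{_slug(phen)}.tsv")
            profiles[phen] = [r.pathway for r in merged]
            stage = "routes"

        stage = "comparison"
        shared = sorted(shared_pathways(profiles)) if profiles else []
        _write_tsv(pd.DataFrame({"pathway": shared}), outdir / "shared_pathways.tsv")

        stage = "networks"
        manifest_nets: dict[str, Any] = {}
        if shared:
            memberships = {name: coll[name] for name in shared}
            targets = {g.label_of(t) for t in g.nodes_in_layer(LayerTag.TARGET)}
            tp = build_tp_network(memberships, targets)
            ctp = build_ctp_network(comp_targets, tp)
            for name, net in (("tp_network", tp), ("ctp_network", ctp)):
                export_network(net, "sif", outdir / f"{name}.sif")
                export_network(net, "graphml", outdir / f"{name}.graphml")
                manifest_nets[name] = {"nodes": net.n_nodes, "edges": net.n_edges}
        export_network(g, "sif", outdir / "hctp_network.sif")
        export_network(g, "graphml", outdir / "hctp_network.graphml")
        manifest_nets["hctp_network"] = {"nodes": g.n_nodes, "edges": g.n_edges}

        stage = "manifest"
        import networkx
        import numpy
        import scipy

        manifest = {
            "config": cfg.model_dump(),
            "seed": cfg.seed,
            "versions": {
                "herbnet": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "networkx": networkx.__version__,
            },
            "counts": {
                "components": len(comp_targets),
                "targets": len({t for genes in comp_targets.values() for t in genes}),
                "pathways": len(coll),
                "phenotypes": len(phenotypes),
                "shared_pathways": len(shared),
                "routes": route_counts,
            },
            "networks": manifest_nets,
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except HerbnetError as exc:
        exc.args = (f"pipeline stage '{stage}' failed: {exc}",)
        raise


def write_dataset(
    g: LayeredGraph, coll: PathwayCollection, outdir: str | Path, extra: dict[str, Any] | None = None
) -> Path:
    """Write a graph + gene sets as TSV/GMT files plus a ready-to-run config.

    Used both to export the packaged fixture and to persist generator
    output; ``extra`` lands in ``ground_truth.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    edge_files = []
    for pair in _EDGE_FAMILIES:
        rows = [e for e in g.edges if g.layer_of(e[0]) is pair[0] and g.layer_of(e[1]) is pair[1]]
        if not rows:
            continue
        fname = f"{pair[0].value.lower()}_{pair[1].value.lower()}.tsv"
        write_edges(g, pair, out / fname)
        edge_files.append(
            {"path": str(out / fname), "source_layer": pair[0].value, "target_layer": pair[1].value}
        )
    write_gmt(coll, out / "pathways.gmt")
    config = {"edges": edge_files, "gmt": str(out / "pathways.gmt"), "outdir": str(out / "results")}
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    if extra is not None:
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(extra, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return out


def simulate(params: GeneratorParams, outdir: str | Path) -> Path:
    """Generate a synthetic dataset and persist it as a runnable directory."""
    g, coll, truth = generate_graph(params)
    return write_dataset(
        g,
        coll,
        outdir,
        extra={
            "planted_pathway": truth.planted_pathway or "none planted",
            "planted_phenotype": truth.planted_phenotype or "none planted",
            "query_genes": list(truth.query_genes),
            "seed": params.seed,
        },
    )


def export_fixture(outdir: str | Path) -> Path:
    """Write the packaged red-ginseng fixture as TSV + GMT files."""
    g, coll = build_red_ginseng_fixture()
    return write_dataset(g, coll, outdir)
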