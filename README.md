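# herbnet

Network-pharmacology analysis of multi-component herbal supplements on a
layered herb–component–target–pathway–phenotype knowledge graph. The
package is aimed at systems-biology and natural-products researchers who
want to go from "which genes does each constituent touch?" to "which
signaling pathways and clinical phenotypes does the preparation act on,
and through which routes?" — with every step scriptable, seeded, and
tested.

## What it computes

Given a layered graph *G* (herb → components → targets → pathways /
phenotypes) and pathway gene sets in GMT format, four analyses run in
sequence:

1. **Phenotype association by random walk with restart.** Starting from
   the component-associated target genes, signal propagates by

   *F*<sub>t+1</sub> = α *F*<sub>t</sub> *A* + (1 − α) *F*<sub>0</sub>

   where *A* is the row-normalized (direction-blind) connectivity matrix,
   *F*<sub>0</sub> the uniform start distribution, and α the rate-control
   factor (default 0.7). Iteration stops when the L1 change falls below a
   threshold (default 10⁻⁶); an exact linear solve of
   *F*(I − α*A*) = (1 − α)*F*<sub>0</sub> serves as an internal oracle.
   Each phenotype's score is reported raw and normalized against a
   degree-proportional baseline restart, correcting for hub bias.

2. **Route exploration.** All component → target → entity routes relevant
   to a queried phenotype are enumerated, and each route scores the mean,
   over its nodes, of the fraction of routes containing that node:
   score = (1/n) Σᵢ count(routes with node i)/count(routes). Per terminal
   entity only the best route is kept, sorted by score.

3. **Pathway over-representation.** For each component's route targets,
   a one-sided Fisher exact (upper-tail hypergeometric) test against each
   GMT gene set; only pathways with ≥ 1 overlapping gene are reported.
   Per-source tables are consolidated spreadsheet-style (overlap count
   desc, then p asc, then name; first occurrence per pathway kept) and
   truncated to a top-K (default 100).

4. **Comparison and network construction.** Per-phenotype pathway
   profiles are intersected to find pathways acting on *all* phenotypes;
   two herbs' shared sets can be differenced to find herb-exclusive
   pathways. The bipartite target–pathway (T-P) and tripartite
   component–target–pathway (C-T-P) networks are rebuilt and exported as
   SIF/GraphML, with degree rankings to surface hub targets and pathways.

Two data sources ship with the package: a **red-ginseng fixture** (5
signature components — ginsenosides Rg1, Rb1, Re, notoginsenoside R1, and
salicylate — 37 target genes, 9 signaling pathways, 4 metabolic-health
phenotypes, from published gene lists) and a **seeded synthetic
generator** that emulates a compound–target knowledge base with a planted
over-enriched pathway and a planted high-connectivity phenotype as
recoverable ground truth.

## Worked example

```sh
herbnet run --fixture --outdir results/fixture
```

writes phenotype scores, ranked routes, enrichment tables, the shared
pathway set, and SIF/GraphML networks. On the fixture,
`phenotype_scores.tsv` contains:

```
node                                     score     raw_score  baseline
PHENOTYPE:blood circulation             0.866556  0.054343   0.062712
PHENOTYPE:diabetes mellitus             0.866556  0.054343   0.062712
PHENOTYPE:hyperlipidemia                0.866556  0.054343   0.062712
PHENOTYPE:menopausal symptoms in women  0.866556  0.054343   0.062712
```

All four phenotypes tie exactly — the fixture wires every target to every
phenotype uniformly (per-phenotype target lists are not published), so
identical scores are the correct answer and a useful sanity check. The
normalized score below 1 says these nodes receive slightly *less* walk
mass than their degree alone would predict (the walk restarts at targets,
not at phenotypes).

The top ranked routes for blood circulation
(`routes_blood_circulation.tsv`):

```
component           target  terminal                   score
notoginsenoside R1  AKT1    blood circulation          0.251046
notoginsenoside R1  AKT1    T-Cell Receptor Signaling  0.193863
notoginsenoside R1  AKT1    Th1-Cell Differentiation   0.192469
```

AKT1 is the only gene hit by all five components, so routes through it
dominate. The consolidated enrichment table ranks
"Natural Killer Cell Activation through ITAM-Containing Receptors"
first (9 of notoginsenoside R1's 19 route targets among its 10 members,
p = 8.6 × 10⁻³, universe of 35 pathway genes). The rebuilt T-P network
has 75 edges and pathway degree sequence 11, 10, 10, 9, 9, 9, 8, 5, 4,
topped by "Vascular Endothelial Cell Activation by Growth Factors"
(degree 11) — matching the published connectivity values.

Synthetic data works the same way:

```sh
herbnet simulate --out data/sim --seed 7
herbnet run --config data/sim/config.yaml --outdir results/sim
```

Other subcommands (`rwr`, `routes`, `enrich`, `compare`, `export`) expose
the individual stages; see `herbnet --help`.

## Layout

- `src/herbnet/graph.py` — layered graph model, TSV/SIF/GraphML I/O
- `src/herbnet/genesets.py` — GMT gene-set collections
- `src/herbnet/synthetic.py` — packaged fixture + synthetic generator
- `src/herbnet/randomwalk.py` — RWR solver and closed-form oracle
- `src/herbnet/paths.py` — route enumeration and path scoring
- `src/herbnet/enrichment.py` — Fisher ORA, consolidation, top-K
- `src/herbnet/compare.py` — pathway intersection/difference, T-P/C-T-P
- `src/herbnet/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
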