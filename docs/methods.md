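# Methods

## The model

herbnet analyzes how a multi-component preparation acts on clinical
phenotypes through a layered knowledge graph with six node kinds: HERB,
COMPONENT, TARGET (gene/protein), PATHWAY, BIOPROCESS, and PHENOTYPE.
Edges are restricted to adjacent layers (herb→component,
component→target, target→{pathway, bioprocess, phenotype},
pathway→phenotype). Edge direction records provenance only; every
connectivity-based quantity — node degree, the random-walk transition
matrix — treats edges as undirected, because "degree" here means the
number of connections a node participates in, not its out-edges. Gene
identifiers are normalized to uppercase HGNC-style symbols on entry
(protein-style spellings such as "TNF-α" map to "TNF"), and node ids
embed the layer (`PATHWAY:...`) so labels can never collide across
layers.

## Random walk with restart

The propagation F(t+1) = α·F(t)·A + (1−α)·F(0) uses the row-vector
convention (F multiplies A on the left). A is built by symmetrizing the
edge set, giving isolated nodes a unit self-loop, and row-normalizing;
this keeps A row-stochastic, so every iterate sums to 1 exactly and the
map is an α-contraction in L1 — the residual after t steps is at most
2α^t, and convergence below any positive threshold is guaranteed for
α < 1. The self-loop convention for dangling nodes was chosen over
teleporting because it is the simplest rule that preserves mass
conservation.

Parameters: `rw.alpha` (default 0.7 — a conventional restart setting for
biological network propagation; the upstream description of the method
leaves it open), `rw.threshold` (default 1e-6, L1), `rw.max_iter`
(default 10,000, far above the ~log(threshold)/log(alpha) steps actually
needed). The closed-form fixed point F(I − αA) = (1−α)F(0), solved
directly, is kept as an exact oracle; the iterative and direct solutions
agree to within ten times the threshold in the test suite.

"Normalized" phenotype scores: raw converged scores favour high-degree
nodes regardless of the start set, so each phenotype's raw score is
divided by the score the same node receives when the restart vector is
degree-proportional — the walk's topology-only baseline (with that
restart choice, scores reflect degree structure alone). A normalized
score above 1 means the start set sends the node more signal than
topology alone explains. Both raw and normalized values are reported.

## Route enumeration and path score

Routes follow component → target → entity (default three layers; a
config option inserts a pathway between target and phenotype for
four-layer routes). Because the graph distinguishes pathway and
bioprocess nodes but the route template names a generic "gene target
entity", both are accepted as terminals. The relevance rule for a
queried phenotype — the genuinely open design point — is: a route counts
if its terminal *is* the queried phenotype node, or if the terminal is a
pathway/bioprocess and the route's target also carries an edge to the
queried phenotype. This makes route corpora per-phenotype (frequencies
are counted within one phenotype's corpus, not globally), matching the
way per-phenotype route counts and pathway lists are reported downstream.

The path score of a route with n nodes is the mean over its nodes of
(count of corpus routes containing the node) / (corpus size). It lies in
(0, 1]; it equals 1 exactly when every node of the route appears in every
route of the corpus (e.g., a singleton corpus), and adding a disjoint
route to the corpus strictly lowers it. Ranking deduplicates per terminal
entity, keeping the highest-scoring route (ties: lexicographically
smallest node sequence), then sorts by score descending with ties broken
by terminal label — all deterministic.

## Enrichment

Over-representation uses the one-sided upper-tail hypergeometric
probability P(X ≥ k) for k overlapping genes between a query of size q
and a pathway of size m in a universe of N genes (scipy's hypergeometric
survival function; verified against exhaustive enumeration of all C(N,q)
draws for N ≤ 20 to 1e-12). One-sidedness is the appropriate reading for
an enrichment context. Only pathways with at least one overlapping gene
are reported. The universe defaults to the union of the GMT collection's
genes and can be switched to the graph's target layer; query genes
outside the universe are dropped with a logged warning.

Consolidation of per-component (or per-phenotype) tables sorts by overlap
count descending, then p-value, then name, and keeps the first row per
pathway name. The p-value tie-break is *ascending* (most significant
first): the source procedure is described as a descending sort, but a
descending-p order would put the least significant pathways on top,
contradicting the selection of "top" enriched pathways, so ascending is
used deliberately. Top-K truncation defaults to 100; no multiple-testing
correction is applied by default (raw p-values are the published
convention here), with Benjamini–Hochberg available behind a flag.

## Comparison and networks

Per-phenotype pathway profiles are intersected by exact string match
after trimming and case-folding (no fuzzy matching); pathways named as
"/"-grouped pairs are distinct nodes. Herb-vs-herb exclusivity is plain
set difference of the two shared sets. The T-P network connects a target
to a pathway iff the gene is in the pathway's list and in the supplied
target set, dropping pathways left without members; the C-T-P network is
the union of the component→target edges with the T-P edges. Degree
rankings sort a layer's nodes by degree descending, ties lexicographic.

## The packaged fixture

The red-ginseng fixture embeds the published gene lists for the five
signature components and the nine signaling pathways they affect, plus
the four phenotypes of interest (menopausal symptoms in women, blood
circulation, hyperlipidemia, diabetes mellitus). Two deliberate
non-reconciliations: (1) the component-list union is 37 genes while the
pathway-list union is 35 — FOS and JUN appear only on the component side;
both families are stored verbatim and kept as separate edge families.
(2) Per-phenotype target lists are not published beyond a top-10 table,
so the fixture wires all 37 targets to all four phenotypes uniformly and
stores the top-10 table (`TOP10_TARGETS`) as an expected-ranking record,
not as edges. Consequently the four phenotypes are structurally
interchangeable in the fixture, and their random-walk scores tie exactly
— asserted in the tests as a symmetry check rather than treated as a
defect.

## The synthetic generator

The generator emulates the structure of a compound–target knowledge base
feeding this pipeline: one herb, `n_components` components (default 5),
`n_targets` target genes (default 40), component→target edges drawn
independently with `edge_prob` (default 0.1), `n_pathways` gene sets
(default 10) with sizes uniform on `pathway_size_range` (default 4–8),
and the four phenotype labels. Ground truth is planted twice: one pathway
receives `planted_pathway_overlap` (default 5) genes from the
component-hit query set, and one phenotype is wired to
`planted_phenotype_targets` (default 8) component-hit targets while the
other phenotypes receive the same number of edges to targets the
components do not hit. Pathway genes are sampled from a decoy pool
`decoy_pool_factor` (default 5) times larger than the target layer, so a
random pathway's expected overlap with the query is well under one gene
and the planted pathway's overlap of 5 is the kind of unambiguous
over-representation the method is meant to flag. All sampling derives
from a single integer seed through one `numpy` Generator, so identical
seeds give identical graphs. Infeasible plants (more planted genes than
the sampled query contains) raise a parameter error rather than degrade
silently.

What the generator does *not* emulate: the scale of real
compound–target databases (hundreds of compounds, tens of thousands of
targets), correlated target profiles between chemically similar
components, overlapping pathway memberships, and literature-biased
degree distributions. Passing recovery tests therefore shows the
inference chain is implemented correctly and detects clear planted
signal at fixture scale; it does not certify performance on full-scale
proprietary knowledge graphs, whose headline counts (corpus sizes,
shared-pathway totals, large network node/edge counts) are out of scope
here.

## Numerical and determinism notes

- All iteration orders are sorted; TSV outputs are byte-identical across
  runs with the same seed and configuration.
- The fixture analyses run in well under a second; the 20-seed recovery
  benchmark and the 100-graph oracle comparison run in a few seconds —
  sizes chosen so the whole suite stays interactive.
- Degenerate inputs fail loudly: empty graphs, empty start sets, empty
  route corpora, queries outside the universe, k < 1 truncation, and
  disallowed layer pairs all raise typed exceptions that the CLI maps to
  exit codes (2 config, 3 validation, 4 non-convergence).
- SIF export uses the tab-separated `source links target` dialect with
  bare ids for isolated nodes; GraphML stores layer/label attributes.
  Both round-trip exactly, property-tested on random graphs.
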