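# Methods

This note documents the models, statistics, numerical choices and synthetic
benchmark behind `modulenet`, in the order the pipeline applies them.

## Networks and weights

A network layer is an undirected gene graph with positive edge weights
(1.0 throughout for unweighted layers). The *co-regulation* layer is built
from a binary gene × treatment significance-call matrix: genes a and b are
connected if they are co-called in at least one treatment, with weight

    w(a,b) = c_both / (c_both + c_a_only + c_b_only),

the frequency with which the pair is co-regulated among all treatments that
call either gene. The weight is symmetric, lies in (0, 1], increases in the
number of joint calls and decreases in each exclusive call count.

The *combined* network is the weighted union of the layers after rescaling
each layer so that every layer contributes the same total edge weight
(constant 1.0 — only the ratio between layers matters for any
cut-ratio-based algorithm); a combined edge's weight is the sum of its
rescaled weights over the layers that contain it. *Common-gene* variants
restrict every layer to the genes present in all layers, then drop nodes
left without edges (per layer by default; a `global` scope drops a node from
every layer if it is isolated in any). On the synthetic benchmark every gene
occurs in every layer, making common-gene variants near-copies of the
originals, so the pipeline leaves them off by default (`common_gene: true`
enables them).

Graph partitioners consume integer edge weights. Co-regulation weights are
scaled-rounded: `iweight = round_half_up(scale · w)` with scale 10, and
edges rounding to 0 are kept in the network but excluded from the
partitioning view. Combined-network weights are ~1/|E| per layer, so they
are mean-normalised first: `iweight = round_half_up(scale · w / w̄)`, giving
a typical edge the weight `scale`. Unweighted layers use iweight 1.

## Multi-resolution partitioning

For a network of n genes the pipeline partitions at every *k* recorded by
the size plan: candidate k ranges over {2, …, ⌈n/3⌉} with average part size
s(k) = n/k; for every integer target size i from 3 to ⌊n/2⌋ the k with s(k)
nearest to i is recorded (ties resolve to the larger k, i.e. the finer
partition). Each distinct recorded k is partitioned once.

The bundled partitioner is contract-based — any backend producing a valid,
balanced, seed-deterministic partition that is locally optimal under
single-node moves is conformant. The default implementation:

1. **Greedy graph growing.** Each part grows from a random unassigned seed
   node, repeatedly absorbing the unassigned node with the strongest
   (weighted) connection to the part, until the part reaches the average
   load n/k. It then *overshoots* toward the balance cap, but only while the
   next candidate is strongly attached (connection ≥ 3× the mean edge
   weight): a cohesive group touched by a part is swallowed whole instead of
   being split at the size target, which matters because refinement can
   polish a partition but cannot nucleate a module.
2. **Single-node refinement.** Kernighan–Lin-style passes move any node
   whose connection to another part (within the balance cap,
   ⌈1.1 · n/k⌉ by default) strictly exceeds its internal connection, until a
   pass makes no move (≤ 10 passes).
3. **Restarts.** The lowest-cut partition of 16 seeded attempts is kept.

An earlier multilevel variant (heavy-edge-matching coarsening) was tried and
dropped: on flat-weight graphs the matching merges across module borders as
often as within them, and the projected partitions were worse than greedy
growing at the finest level.

## Subgraph extraction and validation

Each part contributes at most one candidate subgraph: the largest connected
component of its induced subgraph (ties broken deterministically), kept only
if it has more than two nodes. Candidates with identical gene sets across
the whole multi-resolution run are collapsed, merging their k-of-origin
provenance.

Because the partitioner always splits the entire graph, some parts are
artefacts of the requested k. Validation compares, per candidate, the mean
shortest-path distance between its own genes against the mean distance to
each other subgraph of the same partition (one observation per neighbour),
with a one-tailed one-sample t-test (alternative: intra < inter). Distances
use Dijkstra with unit lengths on unweighted layers and 1/weight on weighted
layers, so strongly co-regulated pairs are close; unreachable pairs are
treated as missing, not infinite. Candidates with p ≥ 0.05 are discarded;
candidates with fewer than two finite inter-subgraph means (or a zero-
variance degenerate sample, resolved by direct comparison) are kept with a
not-applicable flag. The whole-network distance matrix is computed once per
network and shared across all of its partitions; a vectorised two-matrix-
product form computes all intra/inter means of a cohort at once and is
asserted in the tests to agree with the per-subgraph definition.

Two density diagnostics accompany every subgraph: edge density
d = 2e/(n(n−1)) and, for weighted layers, weighted density
h = 2w/(w̄·n(n−1)) with w the summed induced weight and w̄ the network's
mean edge weight (h reduces to d when all weights equal w̄).

## Congruence, best hits, merging

Subgraph pairs from different single-data-type networks are compared when
their sizes differ at most ten-fold. The confusion table is TP = |A∩B|,
FP = |A|−TP, FN = |B|−TP and TN = |A∪B|−TP (the congruence convention:
"true negatives" are the non-shared genes of the pair). A p-value is
computed only when TP ≥ 3 and MCC ≥ 0.2: the upper-tail hypergeometric
probability of drawing ≥ TP of A's genes in a |B|-sized sample from the
union of the two source networks' gene sets. (The literal two-subgraph
union would make the test degenerate — the "neither" cell is structurally
zero; a `literal_union` mode retains that construction for comparison.)

One degenerate case deserves note: for *identical* gene sets the congruence
convention forces TN = 0 and every denominator factor pair degenerates. The
generic zero-denominator convention (MCC ≔ 0) would score a perfect match as
the worst possible hit and silently drop it at the MCC pre-filter, so the
congruence MCC returns the perfect-agreement limit 1.0 when TP > 0 and
FP = FN = 0. All other degenerate tables score 0.

P-values are Benjamini–Hochberg corrected over all computed tests of the
run. Per subgraph and opposing network, the significant hit (q < 0.05) with
maximal MCC is flagged its best hit (ties: smaller q, then lexicographic
id); reciprocal best hits are mutually flagged pairs. Best hits form a graph
over subgraphs whose nodes above the 97.5th degree percentile are
*high-degree subgraphs*; together with their best-hit partners they form
*high-degree neighbourhoods*. Each reciprocal pair is merged into a
composite subnetwork: the union of the two gene sets with every layer's
induced edges tagged by source layer, and node/edge betweenness computed
with unit edge lengths regardless of layer weights.

## Enrichment, coverage, controls

The ontology model is a term DAG (is_a and part_of parents, acyclicity
enforced) over the three standard namespaces; annotations are propagated to
ancestors (true-path rule, toggleable) and can be filtered by evidence code
(all / no-IEA / IEA-only). Terms with fewer than two annotated network genes
are ineligible — excluded from testing and from coverage denominators.

Each subgraph is tested against every eligible term: upper-tail
hypergeometric with the network's genes as population, the term's annotated
network genes as successes, the subgraph as the sample. **The BH family is
the full subgraph × eligible-term grid**: tests with an empty intersection
are performed tests with p = 1 and count in the family size m, although only
rows with TP ≥ 2 are materialised (a 0- or 1-gene overlap can never reach
significance at grid-sized m). This matters: pooling only the non-empty
intersections, as an earlier draft did, inflates the effective FDR under
heavy true signal and lets 2–3-gene chance overlaps through. Each result
carries an MCC (shared implementation with the congruence module; the
ordinary zero-denominator convention applies since TN > 0 for any term not
annotating the whole network).

Coverage per namespace = 100 × (eligible terms enriched in ≥ 1 subgraph) /
(eligible terms); "average MCC" is the mean over enriched terms of the best
per-term subgraph MCC. Co-enriched term pairs (two terms over-represented in
the same subgraph) are classified as same-namespace related (one term an
ancestor of the other), same-namespace unrelated, or different-namespace;
pairs co-enriched only in merged reciprocal-best-hit subnetworks (tested
against the combined network's population) and in no single network are the
*novel pairs*. The randomisation control permutes annotation profiles over
the union of network and annotated genes, preserving each profile and every
term's usage while destroying gene alignment; deterministic per seed.
Relative enrichment by term size is, per size bin, the proportion of
MCC ≥ 0.2 enriched terms in the bin minus the proportion of all eligible
terms in the bin — a difference of two unit-sum vectors, so the bin values
sum to zero (not one; the stated formula cannot sum to one, and the zero-sum
form is implemented and asserted).

## The synthetic benchmark

`PlantedDesign` defaults define "bench-A", the study condition for all
end-to-end tests: 500 genes; 8 planted modules of 12 genes; planted-
partition edges with p_in = 0.6 within expressed modules and p_out = 0.02
elsewhere; two unweighted layers ("ppi" expressing modules 0–6, "genetic"
expressing 0–5 and 7) plus a co-regulation layer built from 60 simulated
treatments (each co-regulated module 0–5 active per treatment with
probability 0.3; genes of active modules called with probability 0.9;
background calls 0.02 — roughly the strong-responder rate of a large
expression compendium); annotation dropout 0.1; artefact seeds 11 (layers),
13 (calls), 17 (ontology).

A structural *bridge module* (12 further genes) drives the combined-network
analyses: its edges form a 12-cycle striped across the two unweighted layers
as perfect matchings, so each single layer sees only 2-node components
(below the subgraph size floor) while the combined network sees a connected
module. Bridge-gene pairs are excluded from background edges and calls to
keep the stripes matchings; bridge genes still connect to the rest of each
layer through ordinary background edges.

The ontology (per namespace) has one root, two mid-level terms, a leaf term
per module (including the bridge), three 4-gene *marker* terms per planted
module (specific functions, is_a children of the leaf, annotating random
4-subsets), and 2000 unaligned 5-gene background terms. Background term size
is a deliberate choice: partial chance overlaps with 5-gene terms have their
smallest attainable p-value above the BH threshold of the grid-sized family,
and complete capture of all five genes by one spurious subgraph is rare —
so background terms pad the coverage denominators realistically without
coin-flip enrichment noise. (With a handful of background terms the test
pool saturates and every term is "enriched" everywhere; with thousands of
4-gene terms, whole-term chance captures reappear. Both regimes were
measured before freezing this design.) The bridge module carries leaf terms
only: 4-gene subsets of a sparse cycle are rarely captured whole.

What the generator does **not** emulate: heavy-tailed degree distributions
(no degree correction), overlapping modules, correlated noise between
layers, ascertainment bias, and ontology depth beyond three levels. Passing
tests therefore demonstrate that the machinery recovers planted structure
under idealised noise, not performance on real interactome data.

## Problem sizes and runtime

The default benchmark analysis (4 networks × ~41 partition resolutions,
~4 000 retained subgraphs, ~6 100 ontology terms) completes in about one
minute on one CPU; the test suite runs it twice (once shared across
end-to-end tests, once for the byte-identical reproducibility check). All
randomness flows from explicit seeds; every numeric table regenerates
byte-identically from the same configuration.

## Known limitations

- The partitioner is a single-level heuristic; on networks orders of
  magnitude larger than the benchmark a multilevel backend would be faster
  (the contract allows plugging one in).
- Validation keeps not-applicable candidates (too few neighbours for the
  t-test), which slightly favours coarse partitions (small k).
- The co-regulation weight and rounding scheme follow the verbal definition
  of co-regulation frequency; the scale factor (10) is a configuration
  point, as is the co-regulation call threshold when calls are derived from
  a p-value matrix.
- Coverage at FDR 5% retains a small, honest rate of false enrichments;
  comparisons between networks are meaningful only with structural margins
  larger than that noise (the benchmark is designed accordingly).
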