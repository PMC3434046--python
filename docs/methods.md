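# Methods

## Problem and model

Homologous genes in two species are orthologs when their last common
ancestor in the gene tree is a speciation node, and paralogs when it is a
duplication node. `qortho` infers pairwise orthology from nothing but
pairwise sequence similarities (BLAST bit scores, treated as a symmetric
similarity S per unordered protein pair), using a quartet statistic that
approximates where a duplication would sit on the gene tree without ever
building one.

For a candidate pair (x, y) — a bidirectional best hit (BBH) between two
species — and a third species in which x has BBH partner z1 and y has BBH
partner z2 with z1 ≠ z2, the score

    α = ½·min(S(x,z1), S(y,z2)) − ¼·(S(x,z2) + S(y,z1) + S(x,y) + S(z1,z2))

is large when the four genes split into two similarity-coherent clades
{x, z1} and {y, z2}, i.e. when a duplication separates x from y. The
maximum α over all third species is stored per pair; the pair is called an
ortholog when that maximum is ≤ Ω, and also when no species yields a
witness — absence of duplication evidence anywhere is treated as orthology.
The cutoff Ω is the user-facing accuracy/coverage dial.

Assumptions worth being explicit about: bit scores decrease with
evolutionary distance consistently enough for best-hit ranking; a
duplication is only detectable if some third species retains both copies
(a duplication all of whose witnesses were lost is invisible — those pairs
are called orthologs); within one third species, only the pair of BBH
partners of x and y is examined, not all homolog pairs.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| coverage threshold | 0.5 | alignment must cover ≥ 50% of *both* sequences (inclusive) |
| bit-score threshold | 50 | hit kept only if bit score strictly exceeds it |
| Ω (omega) | 20 | ortholog call cutoff on max α (inclusive ≤), bit-score units |
| MCL inflation | 2.0 | granularity of group clustering |
| missing-similarity policy | skip | witness handling when one of the six S values is absent |

Filtering is corpus-wide and happens before best-hit ranking, so BBH,
quartet witnesses, and inparalog detection all see the same quality-screened
similarity store. Within-species hits are retained (inparalogs need them);
self-hits are dropped. Coverage uses the single best HSP span with inclusive
coordinates (|end − start| + 1); reversed minus-frame coordinates are
handled by the absolute span. When both directions of a pair were reported,
the pair's S is the arithmetic mean of the two directional best-HSP bit
scores — symmetric and stable under input reordering.

Missing values among the six similarities of a quartet: the witness is
skipped rather than imputing 0. Imputing would inflate α and manufacture
duplication evidence out of filter artifacts; the alternative policy
(`impute_zero`) is available behind a flag for comparison. No-evidence pairs
carry a distinct sentinel (serialized `NA`), never −∞.

Ties anywhere (best hits, cluster overlap, group ordering, weakest-edge
splitting) are broken by lexicographic identifier so that identical inputs
and configuration give byte-identical outputs on any platform.

## Markov clustering

Groups are MCL clusters of the graph whose edges are called ortholog pairs
weighted by S (edge weight is the only corpus-intrinsic quantity available;
an unweighted variant is a one-line change). The engine column-normalizes
the adjacency with self-loops set to each node's maximum incident weight (a
standard regularization that guarantees convergence), then alternates
expansion (matrix squaring) and inflation (entrywise power 2.0 +
renormalization), pruning entries below 1e−5 while always protecting each
column's maximum. Iteration stops when the largest entrywise change drops
below 1e−8. Clusters are read off attractor rows; a node attracted by
several clusters goes with the cluster containing the smallest member id.
Clusters spanning ≥ 3 distinct species become orthologous groups, numbered
`QTS_1, QTS_2, …` by decreasing size; clusters on ≤ 2 species are dropped
from the group table (their pairs remain in the pairwise output). The test
suite checks the engine against an independently coded dense implementation
on random graphs.

Consensus annotation is facet-wise (gene symbol, description, each GO
accession independently): a value is adopted when shared by strictly more
than 80% of *all* group members — unannotated members count in the
denominator, since the group, not its annotated subset, is being
characterized. A flag restricts the denominator to annotated members for
users who prefer the laxer reading.

## Inparalog groups

The defining condition is set-level: every internal pairwise similarity of
a same-species set must exceed the similarity between any member and any
protein of any other species. The condition does not dictate an algorithm,
so construction proceeds by (1) keeping within-species edges whose S
exceeds both endpoints' external ceilings, (2) taking connected components
of size ≥ 2, and (3) verifying each component against the set condition —
a missing internal pair counts as similarity 0, because a set cannot claim
cohesion on absent evidence — splitting failures at their weakest internal
edge and re-testing. Every emitted group is re-verified post hoc against
the literal condition, independent of the construction path. Singletons are
not emitted. Inparalogs extend each called ortholog pair (x, y) to the
co-ortholog product {x ∪ inparalogs(x)} × {y ∪ inparalogs(y)}.

## Synthetic corpora

The simulator exists so every stage has ground truth. A species tree is
drawn as a clock-like (ultrametric) tree by coalescent-style pairwise
merges with exponential waiting times (height scale 0.4, giving typical
root heights near 0.7). Clock-like trees were chosen deliberately:
similarity ranks then mirror divergence-time ranks, so the truth labels are
exactly recoverable in the noise-free limit and any failure is a pipeline
defect, not a tree artifact. One gene enters each family at the root and
duplicates (rate 0.3/unit time) or dies (rate 0.1) along each branch;
lost lineages are pruned and unary nodes suppressed. Truth follows from
the event-labeled gene tree: a pair is orthologous iff its LCA is a
speciation; true inparalog sets are maximal duplication clades whose
surviving leaves all belong to one species (when losses erase a family
everywhere else, the duplication is observationally more recent than every
speciation separating the clade from surviving genes of other species, so
such clades qualify).

Similarities are generated directly from gene-tree path distance d as
`S = max(0, 500·exp(−2·d) + Normal(0, 10))`, symmetrized, with pairs at or
below the bit-score floor of 50 omitted — emulating hits the search would
not report. The scale mimics protein bit scores: a few hundred between
close relatives, decaying below the reporting floor for the most divergent
pairs, with a pre-/post-duplication score ratio large enough for α to
resolve. There is no sequence evolution, alignment, rate heterogeneity,
horizontal transfer, or gene conversion; coverage fractions are emitted as
1.0. Passing tests therefore demonstrate the correctness of the scoring
and clustering pipeline under a faithful distance-monotone similarity
model — not robustness to alignment artifacts, domain shuffling, or
compositional bias in real searches.

Accuracy is measured over the pipeline's own candidate universe: truth-
labeled cross-species pairs that are BBH. Pairs the search never reported
(or that fell below the quality floor) are outside the universe, matching
how such pipelines are evaluated in practice. Zero-denominator ratios are
reported as `NA`.

## Problem sizes and numerical choices

Default test and acceptance corpora use 8 species and 30–50 families
(roughly 300–500 proteins, ~500–900 BBH pairs), which exercises every code
path — duplications witnessed from third species, complementary-loss BBH
paralogs, multi-copy families, inparalog clades — while keeping the whole
suite fast. MCL stochasticity is maintained to 1e−9 per iteration; the α
oracle comparison is exact to 1e−12. Exhaustive-enumeration oracles
(double-maximization BBH, all-witness α, LCA-walk labeling, dense MCL) are
implemented separately in the test suite and never share code with the
pipeline paths they check.

## Known limitations

- A duplication with no surviving two-copy witness species is undetectable
  by construction; such pairs are called orthologs (the method's documented
  accuracy/coverage tradeoff, governed by Ω).
- Only the BBH-partner pair per third species is examined as a witness;
  enumerating all homolog pairs in the third species is an extension point
  left closed.
- The simulator's similarity model is distance-monotone by design; it does
  not probe BBH failure modes caused by non-clock rate variation.
- Group formation discards two-species clusters from the group table by
  definition; their orthology evidence is only in the pairwise output.
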