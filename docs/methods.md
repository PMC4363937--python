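# Methods

`coexnet` implements an index-gene-centered strategy for nominating
co-signaling genes from a small two-group expression experiment and a
confidence-scored interaction catalog. The chain is: rank genes by
co-expression with an index gene and by class contrast → extract top-k gene
modules → confidence-filter interaction edges and assemble a network around
the module union → characterize its topology against an Erdős–Rényi
baseline → rank hubs and bottlenecks → detect dense complexes → annotate
them by over-representation → nominate candidates at the intersection of
those lines of evidence.

## Ranking and module extraction

The index-gene score of gene *g* is the Pearson correlation r(g, index)
across all samples (Spearman available). The index gene is excluded from
its own ranking; zero-variance genes score 0; a constant index profile is
an error. The class-contrast score is the signal-to-noise ratio
(μ_A − μ_B)/(σ_A + σ_B), with each class standard deviation floored at
max(0.2·|μ|, 1e−8) — the conventional floor that keeps near-constant genes
from dominating. Modules are top-k slices (default k = 50, the strategy's
stated module size), with boundary ties broken by gene identifier so
extraction is deterministic.

## Enrichment score

For a gene set against a ranked list of length N, the running sum gains
|score|^p / Σ_hits |score|^p at each member ("hit") and loses 1/(N − N_hits)
at each non-member. The enrichment score (ES) is the signed extremum of
this walk; at p = 0 it is exactly the two-sample Kolmogorov–Smirnov
statistic between hit and miss rank positions (regression-tested against an
independent empirical-CDF oracle). The weight exponent defaults to p = 1.
Normalization uses a permutation null: NES = ES / mean(|same-sign permuted
ES|), empirical p with a +1 pseudo-count, and an FDR q as the ratio of
pooled-null to observed tail proportions, clipped to [0, 1]. The default
null permutes gene-set membership rather than phenotype labels: with three
samples per group only 10 distinct label permutations exist, so phenotype
permutation is degenerate (it remains available for larger designs).
Permutation ES values are computed by a closed-form O(k) evaluation at hit
positions — between hits the running sum decays linearly, so the extremum
can only occur immediately before or after a hit.

## Network assembly

Edge lists are 4-column TSV (gene, gene, confidence ∈ [0,1], evidence
type). Malformed lines (missing columns, out-of-range confidence,
self-loops) are counted and reported, not fatal. The confidence filter
keeps edges **≥ 0.70**; the boundary value is retained (the source
convention states both "greater than 0.7 kept" and "less than 0.7
rejected", leaving equality open; we keep it and log the choice).
Assembly merges duplicate undirected edges keeping the maximum confidence,
drops self-loops, and by default expands the seed union to first neighbors
— the reconstructed networks in this style of analysis are several times
larger than their seed lists, which implies interactor expansion. Isolated
seeds remain as nodes.

## Topology conventions

**The mean degree is reported as k = L/N — edges per node, half the
conventional 2L/N.** This nonstandard convention is deliberate: it is the
only arithmetic consistent with every column of the published topology
table this module mirrors (6554/1717 → 3.8, 5203/1313 → 3.9, 851/230 → 3.7,
4488/1870 → 2.4). Printed values are truncated, not rounded (3.96 appears
as 3.9). The mean clustering coefficient averages Watts–Strogatz local
clustering over nodes of degree ≥ 2 only; degree-0/1 nodes have no
neighbor pair to close and are excluded rather than counted as zeros (a
`coverage_note` records the convention, and the alternative is one flag
away). The characteristic path length is the mean BFS distance over all
unordered connected pairs of the largest component — disconnected pairs
would otherwise contribute infinite distances. The ER baseline is uniform
G(n, m) with exactly m edges; closed-form expectations are k = m/n,
C = m/C(n,2), and l ≈ ln(n)/ln(k) (the small-world approximation under the
same k convention, which reproduces the published baseline value 4.15 when
truncated to two decimals). The published baseline clustering value 0.015
matches neither closed form (m/C(n,2) = 0.032, k/n = 0.016); we report the
simulation estimate and the closed form and do not claim to reproduce it.

## Hubs, bottlenecks and candidate nomination

Hubs are ranked by degree and bottlenecks by exact unnormalized betweenness
centrality (Brandes, via networkx; verified against an exhaustive
shortest-path enumeration oracle on small graphs). Shortest paths are
unweighted BFS by default; the weighted mode runs Dijkstra with edge cost
1 − confidence + 1e−6 so high-confidence routes are preferred. A candidate
is a node that (a) is within the top-h hubs or top-b bottlenecks (defaults
h = b = 10), (b) lies within max_dist (default 2) of the index gene, and
(c), when any detected motif contains the index gene, shares such a motif.
The motif criterion is waived when no motif contains the index, so sparse
neighborhoods still yield candidates. Output is ordered by (distance, best
rank, node id) and annotates which criteria each candidate met. The index
gene itself is never nominated.

## Dense-complex detection

Complex detection follows the molecular-complex (MCODE-family) scheme:
each vertex is weighted by the highest k-core of its **open** neighborhood
(core number × that core's density; a vertex of a clique K_n weighs n − 2);
complexes grow from the heaviest unvisited seed, admitting unvisited
neighbors with weight ≥ seed_weight × (1 − VWP), VWP defaulting to the
published 0.2. Each vertex joins at most one complex. Two deliberate
choices: (1) zero-weight vertices never seed — a weight-0 seed's threshold
is 0, so it would sweep up arbitrarily sparse structure (a bare path would
become a "complex"); (2) the haircut is the iterated 2-core of the complex
restricted to the seed's component, which guarantees post-haircut complexes
are internally connected with minimum internal degree 2. Complexes under 3
members are discarded; survivors are scored density × size and ranked, the
reporting stage keeping the top 10 by default. Note that seeded expansion
crosses any bridge whose far endpoint meets the weight threshold, so two
equally dense cliques joined by a single edge merge into one complex — a
property of the algorithm family, not a defect; the recovery benchmarks
use distinct clique sizes so expansion thresholds keep complexes apart.

## Over-representation

Motif annotation uses the upper-tail hypergeometric test P(X ≥ overlap)
with Benjamini–Hochberg adjustment across the collection (equivalent to
one-sided Fisher exact; regression-tested against it). The default
universe is the analysis network's node set, matching the within-network
framing of per-motif annotation tables; a genome-scale universe can be
passed instead. Term members outside the universe are clipped with a
warning. The original analysis style used a Bayes-factor ranking service;
that service is defunct and its priors unpublished, so the hypergeometric
test stands in — rows are ordered by q, then p.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the structure the pipeline assumes, with ground
truth recorded for scoring:

- **Expression** (default 1000 genes, 3 control + 3 stressed samples,
  matching the pooled-sample study design): a latent factor per sample;
  the index gene's profile *is* the factor; each of the 50 positive-module
  genes is ρ·factor + √(1−ρ²)·noise_sd·ε (ρ defaults to 0.9), negative-
  module genes carry the negated factor, and differential sets receive a
  ±effect_size shift (default 1 log2 unit) in the stressed class. With
  noise_sd = 1 the expected correlation with the index gene is exactly ±ρ;
  with ρ = 1, noise_sd = 0 it is exactly ±1. Values are post-log additive
  Gaussian around a baseline of 8: downstream statistics are ranks and
  correlations, which are scale-robust, so probe-level array simulation
  would add nothing testable.
- **Interactions**: disjoint planted cliques (default 8 of size 4–6) plus
  a designated hub attached once to each clique (guaranteeing top degree),
  with true-edge confidences Beta(8,2) and decoy confidences Beta(2,8) —
  chosen so the 0.70 cutoff is discriminative — and decoys as uniform
  random non-edges (default 30% of the list). Bare floats give point-mass
  confidences for exact boundary tests.
- **Annotations**: one GMT term per planted clique (± contamination) plus
  random background terms drawn without replacement from the universe.

Not emulated: probe-level effects, normalization artifacts, batch effects,
correlated noise between background genes, and any real biology in the
identifiers. Passing the recovery benchmarks therefore demonstrates that
the *machinery* recovers planted structure under the stated noise model —
not that real adrenal-medulla data would yield the same lists.

### Sample size and the recovery benchmark

At the study's own 3-vs-3 design (6 samples), the sample Pearson
correlation has Fisher-z standard deviation 1/√3 ≈ 0.58, so planted-module
genes at ρ = 0.9 overlap heavily with the upper tail of ~950 background
correlations: expected top-50 recovery is ≈ 78% and no ranking method can
do better from 6 exchangeable samples. The recovery benchmark therefore
uses 10 samples per group, where the estimator is informative (recovery
≥ 90% with wide margin); the unit suite additionally freezes the 3-per-group
value at a fixed seed so the small-sample ceiling itself is regression-
tested. The candidate-nomination benchmark plants its trusted edges as a
0.95 point mass so the geometry it scores survives the 0.70 filter; under
Beta(8,2) confidences roughly a fifth of true edges fall below the cutoff
and the benchmark would measure filter erosion rather than the nomination
logic.

## Numerical choices and degenerate inputs

- Ranked lists sort by (−score, gene id): fully deterministic under ties.
- All-zero hit weights at p > 0 fall back to uniform hit increments.
- The running sum closes at 0 within 1e−9 (both CDFs normalized); ES is
  clipped-free and always in [−1, 1].
- A gene set with no overlap with the ranked list, or covering it
  entirely, is an error; members absent from the list are dropped with a
  warning.
- Zero same-sign permutations leave NES undefined and flagged
  (`nes_defined = False`), never silently dropped.
- `er_expectations` with m ≤ n has no defined path-length approximation
  (log base ≤ 1); it returns NaN with a warning.
- Empty networks are errors for summaries and centrality; an empty
  candidate list is a valid result.

## Problem sizes

Default test and acceptance runs use 100–1000-gene expression matrices,
networks of 80–250 nodes, 99–1000 permutations, and 100-seed benchmark
sweeps; these sizes give stable statistics for every check while keeping
the full suite around half a minute on one CPU.

## Known limitations

- Identifier matching is exact string match after whitespace trimming; no
  alias or ortholog resolution.
- Single-membership complexes only (no overlap mode); no directed variant.
- The hub metric is degree and the bottleneck metric betweenness; other
  centralities (MNC, DMNC, EPC) are out of scope.
- GO-graph ancestor propagation and live pathway-database access are out
  of scope; annotation collections are consumed as GMT.
- Phenotype permutation is provided but statistically weak below ~7
  samples per group.
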