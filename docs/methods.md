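# Methods

`rhizonet` reconstructs a bacterial protein–protein interaction (PPI) network
from two computational evidence streams, assesses its reliability against
degree-preserving null models, and dissects it into physiological-state
subnetworks and symbiosis-related functional modules. This note documents the
models, the parameters that matter, the synthetic data the pipeline is tested
on, and the numerical choices made where the design was genuinely open.

## Interolog transfer

An interolog is a PPI inferred in the target species because the orthologs of
the two proteins interact in a reference species. Given a reference edge
(A, B) and an ortholog map, every target pair (a, b) with a homologous to A
and b to B is predicted; when one target protein is homologous to both ends
the prediction is a self-interaction, which is kept and flagged. Ortholog
groups follow the InParanoid table shape (seed orthologs score 1.0,
inparalogs in (0, 1)); transfer crosses **all** group members at or above a
configurable inparalog-score threshold (default 0.0, i.e. include all), and
the edge confidence is the product of the two member scores, max-aggregated
when several reference edges support the same pair. A
bidirectional-best-hit (BBH) builder over a two-direction similarity table is
provided as an orthology fallback; ties for best hit all become groups.

For cross-species experimental corpora (as opposed to single reference
species), each transfer records its supporting reference pair so that a
reviewed-sequence restriction can be applied: such an edge is kept only when
**both** supporting proteins are in the reviewed set. Requiring both (rather
than either) is the stricter of the two readings and is configurable
(`require_both=False`).

## Domain-based prediction

Domain hits (HMMER/Pfam shape) pass the filter only with score > 20,
e-value < 1e-5 and model coverage > 0.9 — all strict, exactly as stated.
Coverage, when not explicit, is (hmm_to − hmm_from + 1) / model_length
(model coverage, not query coverage).

Domain–domain interactions (DDIs) come from two routes:

* **Association route.** For a domain pair (X, Y), the score is the fraction
  of candidate protein pairs in an experimental corpus that actually
  interact, where a candidate pair has X on one partner and Y on the other.
  A self-pair (p, p) is a candidate only when X ≠ Y both sit on p; a
  homotypic (X, X) candidate needs two distinct carriers. Scores therefore
  live in (0, 1]; pairs with score > 0.5 are retained.
* **Structural route.** A 3DID-style table is consumed as-is (score > 0).

The combined set is
`(association ∩ structural) ∪ {association ≥ 1} ∪ {structural > 2}`.
The middle cut is printed as "> 1" in the source conventions, but on a
fraction-valued scale nothing exceeds 1; it is applied as ≥ 1 (only
perfectly-associated pairs qualify), with a `strict_gt_one` flag restoring
the literal inequality. Target PPIs are then predicted for every protein
pair (self-pairs allowed) carrying a combined DDI; the evidence score is the
best supporting DDI score.

## Assembly and refinement

Prediction sources merge by unordered-edge union with concatenated evidence
(associative, commutative, idempotent on edge sets). Before
dominating-set analysis the network is refined: self-interactions are
removed, then nodes left without edges are dropped. Self-loop removal alone
never changes the node set; the isolated-node drop is a separate,
documented step of the refinement.

## Quality assessment

Three per-edge signals are compared against an ensemble of degree-preserving
random networks:

* **Colocalization** — fractions of edges whose endpoints share a known
  subcellular location, differ, or include an unknown location.
* **Functional similarity** — Wang's GO semantic similarity. Each term's
  ancestors receive semantic contributions decaying by 0.8 per `is_a` and
  0.6 per `part_of` edge (the G-SESAME constants; configurable), the
  similarity of two terms is the normalized overlap of their contribution
  sets, and protein-level similarity is the best-match average, computed per
  GO namespace and averaged over namespaces where both proteins carry terms.
  Pairs with no usable annotation are excluded rather than scored 0.
* **Coexpression** — Pearson correlation of log expression profiles
  (log-scale because microarray-style signals are positive and
  multiplicative); genes with constant profiles are excluded so no NaN
  enters the distributions.

The null model rewires edges by Maslov–Sneppen double-edge swaps (default 10
successful swaps per edge), holding self-loops fixed and rejecting proposals
that would create a loop or duplicate edge, so the degree sequence is
preserved exactly and the graph stays simple; swap-rigid graphs (e.g. a
triangle) return unchanged. The swap loop is implemented here rather than
delegated, because the contract on rigid and tiny graphs must be "identity",
not an error. Real-versus-null score distributions are compared by a
one-sided Wilcoxon rank-sum test with null edges pooled across the ensemble
(pooling, rather than per-null testing, is the documented choice).

## COG pair enrichment

Edges whose endpoints are both COG-annotated are counted into a symmetric
category-pair matrix; a protein with several COG letters contributes to each
combination of the pair (an unweighted cross-product; a 1/(|c_u|·|c_v|)
weighting is available by flag). Within-category pairs land on the diagonal,
counted once. Against `n_nulls` rewired networks (default 1000; tests and
the calibration check use 100) the per-cell z-score is
Z_ij = (A_ij − ⟨Rnd_ij⟩)/σ_ij. Cells with σ = 0 report Z = 0 when the
observed count equals the null mean and a signed infinity sentinel
otherwise; sentinels serialize as `inf`/`-inf` and are excluded from scaling.
Under the self-null (a network scored against rewires of itself) the
per-cell Z is approximately standard normal, so the calibration quantity is
the **signed mean** over finite cells, which is ≈ 0 for an unbiased
implementation; the mean of |Z| tends to E|N(0,1)| ≈ 0.8 and is not a
calibration failure.

## Topology and controllability

Metric conventions match the Cytoscape Network Analysis plugin: clustering
2·triangles/(k(k−1)) with 0 for k < 2; closeness = reciprocal mean distance
to reachable nodes (component-local); betweenness normalized by
(n−1)(n−2)/2 within each component; per-node average shortest path length
over reachable nodes; self-loops ignored throughout.

The degree exponent γ of y = a·x^(−γ) is estimated two ways: least squares
on log10(count) vs log10(degree) (zero-count bins dropped, R² reported) and
the discrete maximum-likelihood approximation
γ̂ = 1 + n·[Σ ln(x_i/(x_min − ½))]⁻¹. The default x_min is 1 to span the
full distribution; note the continuous approximation is least biased for
x_min ≥ 2, and the regression estimator needs near-exact histograms (it is
badly biased by one-count tail bins on raw samples).

The minimum dominating set solves min Σx_v subject to
x_v + Σ_{u∈N(v)} x_u ≥ 1, x ∈ {0,1}. The exact solver is a bitmask
branch-and-bound: greedy upper bound first, then branching on the closed
neighborhood of the first uncovered vertex, lexicographic order throughout
for reproducibility. It is exact up to a configurable node limit (default
60; verified against exhaustive subset search on all graphs ≤ 15 nodes) with
the greedy cover as fallback on larger networks. Only the MDS cardinality is
contract-stable — optimal sets are generally non-unique — so membership is
reported but not asserted. Fisher one-sided enrichment of MDS membership per
COG category reports raw and Benjamini–Hochberg-adjusted p-values; the
compatibility flag uses raw p < 0.01.

## State subnetworks

A gene is expressed in a state only when strictly more than 80% of its
replicates have detection p ≤ 0.06 (both boundaries as printed: the
fraction is strict, the p cut inclusive); its level is the mean signal over
exactly the passing replicates. A state subnetwork keeps edges whose
endpoints are both expressed. The transcription-level difference
D_ij = |s_i − s_j|/(s_i + s_j) ∈ [0, 1) is compared between interacting
pairs and the control group of **all n² ordered pairs including self-pairs**
— the n² convention is pinned by the printed control-group sizes
(3650² = 13,322,500 and 1777² = 3,157,729) — by a one-sided rank-sum test
(α = 0.01). Per-COG comparisons assign an edge to a category only when both
endpoints carry it (either-endpoint mode by flag).

## Symbiosis core subnetwork and modules

The core subnetwork (SCSNW) keeps every edge touching a curated seed
protein; its node set is the endpoints of kept edges, so first neighbors
enter and the SCSNW is larger than the seed list. Markov clustering runs on
the column-stochastic walk matrix with unit self-loops: expansion (matrix
power 2), inflation (elementwise power, default 2.0, then column
renormalization), pruning below 1e-5, until the maximum entry change falls
below 1e-8 or 100 iterations (non-convergence returns the current clustering
with a flag). Clusters are the connected components of the attractor
structure; they always refine graph components and cover every node.

Key modules are ranked by seed-protein count, then size, then id (top N,
default 9). A Tie-of-Modules (TOM) hub is a node outside every key module
with degree at least the 75th percentile (configurable) and at least one
edge into each of ≥ 2 distinct key modules. These criteria are this
package's reconstruction of the idea "hub outside the modules that ties
several of them together"; all three thresholds are explicit parameters. A
granularity caveat discovered on the synthetic scenarios: at inflation 2.0
MCL tends to absorb a balanced connector hub into one of its adjacent
clusters (at inflation ≥ 4 the connectors separate), so connector recovery
is assessed against the planted partition while clustering quality is
assessed separately by adjusted Rand index.

The conserved-module matcher is a deliberately simple ortholog-guided edge
matcher: an edge (u, v) of module A is matched when (map(u), map(v)) is an
edge of module B; unmatched edges whose endpoints both map become suggested
missing interactions for the other species. It reproduces the
matched-count/suggested-edges reasoning of cross-species module comparison
without any alignment search.

## Synthetic data: what it emulates and what it does not

Every pipeline input can be generated with planted, recoverable structure,
deterministically under a seed (streams are derived as `(seed, stream)`
tuples; byte-identical files on re-run):

* proteome with COG letters from a fixed categorical distribution ("E"
  largest at 12%, "D" rare at 0.5%, ~92% of proteins annotated, 15% with a
  second letter), GO terms from a generated three-namespace DAG, and
  subcellular locations with a configurable unknown fraction (default 0.25);
* reference interactomes (preferential attachment for scale-free degree
  structure, or planted partition for modular structure);
* ortholog group tables with seed orthologs and optional inparalogs, plus
  the exact transferable edge set as ground truth (computed by independent
  nested-loop enumeration, not by the interolog module);
* domain tables whose hit scores straddle the 20/1e-5/0.9 boundaries, an
  experimental corpus whose edges are driven by planted interacting domain
  pairs, and a structural DDI table;
* expression matrices per state: genes of one module share a latent
  per-replicate factor with loading √ρ (so any two module mates have
  log-signal correlation ρ, default 0.8) **and** a shared baseline level
  (individual spread 0.25 in log units), so interacting pairs have both
  correlated profiles and similar levels; detection p-values are
  Uniform(0, 0.06] for expressed genes (probability = detection rate,
  default 0.9 over 15 replicates) and Uniform(0.06, 1] otherwise;
* an SNF scenario: dense planted modules (within-density 0.9, sizes 6–12)
  around seed proteins, sparse between-module edges (0.02), connector hubs
  wired through the seeds of ≥ 2 modules, and loosely attached background
  nodes; module assignment, seed list and connector list ship as ground
  truth.

Not emulated: sequence-level realism, probe-level microarray artifacts,
experimental false-positive structure in reference interactomes, assortative
or spatially constrained degree correlations, and any biological coherence
between GO labels and network structure (GO terms are random, so functional
-similarity validation on synthetic data sits at chance — by design, this
verifies the test's level rather than its power). Passing tests therefore
demonstrate algorithmic correctness and statistical calibration, not that
real data would show the same effect sizes.

## Problem sizes

Default study conditions: 300 target proteins, 2 reference species, ortholog
fraction 0.6, 15 replicates. The test suite and acceptance script scale
stochastic checks to run comfortably on one CPU: oracle equivalences on
100–200 random instances of ≤ 30 proteins, null-model calibration on
60-node networks with 100 rewired nulls over 20 seeds, MCL recovery over 20
seeded three-module scenarios, and MLE recovery from 10,000-sample draws.

## Known limitations

* The association-score definition for PPI-derived DDIs is this package's
  interpretation (interacting fraction of co-carrying pairs); the original
  convention behind the printed 0.5/1 thresholds is not fully specified.
* Exact MDS is exponential in the worst case; above the node limit only the
  greedy bound is produced (reported as such).
* Structural PPI validation through an external structure server is out of
  scope; only its output categories could be ingested.
* MCL granularity (inflation) is a free parameter; module counts and
  connector placement depend on it, as documented above.
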