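# Methods

## The multilayer model

A layer is an undirected weighted gene graph *G* = (*V*, *E*, *w*) with
no self-loops and each unordered pair occurring at most once.  Weights
are interpreted as the probability of the relation existing, so they are
constrained to [0, 1]; the one deliberate exception is the aggregate
layer (below), whose weights are sums.

A multilayer network over layers *L* is the quadruplet
*M* = (*V_M*, *E_M*, *V*, *L*): *V* is the union of the layer node sets,
*V_M* ⊆ *V* × *L* the node-layer pairs actually present, and *E_M* the
intra-layer edges plus inter-layer couplings.  Couplings are
*categorical*: every gene present in two or more layers gets pairwise
coupling edges of one uniform weight (default 1) between all of its
replicas.  Couplings are excluded from degree, strength and aggregate
computations by default — per-layer descriptors are reported as stacked
per-layer quantities, and including couplings would contaminate each
stack with a constant offset per shared gene — but an
`include_couplings` flag adds them for the whole-multilayer descriptors.

The aggregate layer sums the layers' adjacency entries over the full
gene universe (an optional normalization divides by the layer count; off
by default, so the aggregate is the plain sum).  The supra-adjacency
matrix places the layer adjacencies on the block diagonal and coupling
weights off-diagonal, with a fixed ordering: layers in declaration
order, genes lexicographic within each layer.  It is symmetric with zero
diagonal by construction.

A gene absent from a layer simply has no replica there; whole-network
tabulations still list it in every scope with degree/strength 0, so
per-layer stacked tables stay rectangular.

## Ingest

Edge lists arrive as TSV (`gene_a  gene_b  p_value`, header required,
extra columns ignored).  The significance skim keeps edges with
*p* below the threshold (default 0.05) and stores weight 1 − *p*, which
makes the stored weight the probability of existence in [0, 1].
Duplicate unordered pairs collapse to the most significant record
(smallest *p*); self-loops are dropped and counted.  An input that loses
every edge yields an empty layer with a warning rather than an error,
because an empty-but-valid condition is a legitimate analysis outcome.

Scalar tracks (`gene  value`, non-negative) bind to one layer each;
genes without a value get 0 and the binding logs its coverage fraction.
Rendering rules follow the mean-threshold/log-size convention: a gene is
colored "above" iff its value is ≥ the track mean over all genes in the
layer (zeros included; the tie at the mean deterministically counts as
above), and drawn size is `size_base + size_scale · log(1 + v/vmax)`
with `vmax` the layer maximum — max-normalization keeps the argument in
[0, 1] and log1p keeps sizes finite and at least the base for zero
values.  The mutation track carries the number of samples with
mutations per gene; a ratio variant (per tested samples) is a caller
choice, since both are plain non-negative tracks.

## Centrality and correlation diagnostics

Degree is the count of incident edges, strength the sum of incident
edge weights; both satisfy the handshake identities (Σd = 2|E|,
Σs = 2Σw), which the tests enforce on random instances.

HITS hub/authority is computed by alternating power iteration on the
weighted adjacency.  The iteration runs on A + σI with σ equal to the
maximum absolute row sum: the diagonal shift leaves eigenvectors
untouched but makes the dominant eigenvalue strictly largest in
magnitude, so bipartite-like structures — where +λ and −λ tie and the
unshifted iteration stalls between two limit vectors — still converge to
the entrywise non-negative Perron vector.  Scores are normalized to unit
Euclidean norm; on undirected structures hub equals authority and both
equal the principal eigenvector, which the tests verify against a dense
eigen-decomposition on all small random graphs.  Convergence is declared
when the successive-iterate max-abs difference falls below `tol`
(default 1e-9); hitting `max_iter` returns a result flagged
unconverged, with a warning, never silently.  An edgeless structure
yields all-zero scores with a warning.

Whole-multilayer HITS runs on the supra-adjacency matrix; the per-gene
score is the Euclidean norm over that gene's replica scores, which
preserves the unit norm of the gene-level vector.  Whole-multilayer
degree/strength are per-layer sums.

Inter-layer assortativity correlates a per-gene descriptor between every
layer pair, aligning on the gene union with absent genes scored 0 (an
intersection mode is available).  Spearman is Pearson on mid-ranked
vectors.  The diagonal is exactly 1; a pair in which either vector has
zero variance is reported as missing (NaN), never as 0, to avoid
fabricating "no correlation".  Rankings (top-k tables) sort descending
with lexicographic tie-break, so reported tables are reproducible.

## Mutation statistics and enrichment

A SNP with score strictly above the threshold (default 0.7) is a driver;
a score at or below it is a passenger — the boundary case goes to the
passenger side because only strict "above" is defined for drivers.
Records without a score stay in a third, unclassified slot, so summary
tables whose overall counts exceed the driver + passenger sum remain
representable.  Summaries report n, mean, median and sample variance
(n − 1 denominator; a population flag switches to n — the convention
matters when reproducing externally published moment tables).  n = 0
statistics and n = 1 variances are reported missing.

Enrichment is the exact upper-tail hypergeometric probability
P(X ≥ k) with population = the gene universe, successes = annotated
genes, draws = the network's genes, observed = annotated genes in the
network.  The tail is summed in log space (log-binomials via `gammaln`,
combined with `logsumexp`), which stays accurate at the 1e-20-scale
p-values genome-wide tests produce; the tests check it against
exhaustive draw enumeration for all small universes and against an
independent survival-function implementation at larger sizes.  Only the
over-representation tail is computed and no multiple-testing correction
is applied, since a single gene set is tested per condition.

## Synthetic study generator

The generator plants the structure the analysis is designed to detect;
all draws derive from `rng_seed` through named child streams, so output
is byte-identical per config.

* **Conformation layer**: grown around the seed gene by preferential
  attachment (targets drawn with probability ∝ degree + 1; each new gene
  additionally attaches to the seed with probability 0.6), emulating a
  seed-centric Hi-C neighborhood.  The post condition continues the
  growth — the pre graph is a subgraph of the post graph — adding genes
  and seed-attached edges, so the neighborhood strictly densifies around
  the seed.
* **Similarity and interaction layers**: Bernoulli edges with
  probability ∝ u_i·u_j, where the per-gene propensity
  u = mixing·shared + (1 − mixing)·private with log-normal(0, 1)
  factors.  `interlayer_mixing` is the planted truth behind the
  measurable inter-layer degree assortativity: 0 gives independent
  layers, 1 identical propensities.  The scale is bisected so the capped
  probabilities hit the target density exactly in expectation; densities
  above 0.5 are rejected upfront as infeasible for both graph models.
* **Edge significance**: real edges draw p ~ U(0, 0.05) (stored weight
  1 − p), and a 10% fraction of decoy rows draws p ~ U(0.05, 1), so the
  ingest skim at p < 0.05 exactly recovers the declared layers (a
  round-trip the tests enforce).
* **Tracks**: methylation and expression come from a Gaussian copula on
  log-normal margins; the configured correlation is a rank target, and
  the copula parameter is ρ = 2·sin(π·r_s/6), which makes the planted
  Spearman exact.  The default −0.5 encodes the expected
  anti-correlation of promoter methylation and expression.  Mutation
  sample counts are negative-binomial.  Tracks cover 90% of layer genes
  by default so coverage reporting is exercised.
* **Mutation scores**: each SNP is a driver with probability
  `driver_fraction` (default 0.70, the driver share typical of
  seed-neighborhood SNP catalogs in breast cancer); scores draw from
  Beta(48, 2) for drivers and
  Beta(2, 8) for passengers — means 0.96 and 0.20 with variances of
  order 1e-3 and 1e-2, matching the reported magnitudes of
  cancer-weighted pathogenicity scores, with both tail masses across the
  0.7 threshold below 1e-3, so planted class and threshold class agree
  on > 99% of SNPs.
* **Gene sets**: a metabolic set samples 10% of graph genes; the
  disease set is enriched among graph genes (30%) relative to the
  background universe (5%), giving the over-representation test real
  signal.  The default universe holds 20,000 genes, a genome-wide
  reference.

Default sizes emulate an ESR1-centric estrogen-stimulation experiment in
a breast cancer cell line: 114 genes pre-stimulus growing to 353, with
15,611 and 63,689 candidate SNPs.

What the generator does *not* emulate: genomic coordinates, read-level
noise, realistic degree distributions of curated interaction databases,
correlated mutation hotspots, or biological pathway structure.  Passing
tests therefore demonstrate that the pipeline's computations are correct
and its planted statistical signals recoverable — not that the method's
biological conclusions transfer to any real dataset.

## Pipeline and reports

`run_condition` executes ingest → build → attach → diagnose → correlate
→ classify → summarize → enrich in a fixed order; any stage error aborts
with the stage name.  Reports are JSON with sorted keys and carry
SHA-256 digests of every input file, so a report is both reproducible
byte-for-byte and auditable.  `compare_conditions` diffs two reports on
the gene union (absence is explicit in gained/lost lists, never a silent
0) and negates exactly under argument swap.  Layout export is
presentation-only and never feeds any statistic: Fruchterman–Reingold
seeds a Kamada–Kawai refinement on the aggregate layer, connected
components are packed side by side so bounding boxes cannot overlap, and
coordinates are shared across layers.

## Problem sizes and numerical choices

The test suite runs the full study at its default size (353 genes,
~64k SNPs) for the end-to-end checks and scales supporting analyses to
what their statistics need: oracle equivalence on ≤ 8-node graphs (120
instances), planted-mixing recovery over 20 seeds at 300 genes, Beta
mean recovery at 10,000 SNPs — sizes at which the expected Monte-Carlo
error is an order of magnitude below the asserted tolerances.  HITS
tolerance defaults to 1e-9 on the max-abs iterate difference; the
committed fixture study (30/45 genes, seed 7) backs the golden-report
determinism test.

## Known limitations

* Directed or ordinal (temporal) multilayer structures are out of
  scope; layers are undirected and couplings categorical.
* Tensorial multilayer descriptors beyond degree/strength/HITS
  (clustering coefficients, communicability, community detection) are
  not implemented.
* Enrichment is gene-level, as the reference/sample construction
  defines it; weighting genes by their SNP multiplicity is left to the
  caller.
* Upstream processing (peak calling, expression normalization, semantic
  similarity, pathogenicity scoring) is assumed done; the package
  consumes their tabular outputs.
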