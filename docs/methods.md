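# Methods

## Model and procedure

`censignet` treats signature integration as a node-ranking problem on a
context-constrained protein interaction network (PIN).  The underlying
assumptions are: (i) a gene recurring in two or more independently derived
signatures carries real disease signal, while single-signature genes may be
artifacts of platform, protocol or small samples; (ii) among the recurrent
genes, topological importance in the interactome — rather than any further
literature curation — identifies the genes most central to the disease
process; (iii) interactions are adequately modelled as an unweighted,
undirected simple graph (evidence codes and direction are ignored on read).

The pipeline is: support counting over GMT signature collections → support
filter (`min_support = 2` by default) → union of interaction sources with
duplicate edges and self-interactions removed → induced subgraph on the
retained genes → six centralities → per-measure descending rank → top-k
unified signatures (k = 54 by default, matching the size at which competing
integration methods are usually compared).

## Centrality definitions and numerics

* **DC** raw degree (no normalization — only the ranking matters).
* **BC** Brandes' algorithm over unordered pairs, unnormalized; a
  `normalized=True` option divides by (n−1)(n−2)/2 and provably never
  reorders.  Unreachable pairs contribute zero.
* **CC** `1/Σ_j d(i,j)` with the sum restricted to i's connected component;
  the constrained PIN can be disconnected and the reciprocal-of-total-distance
  form is undefined across components.  Nodes with no neighbor score 0.  A
  `harmonic` variant (`Σ_j 1/d(i,j)`) is available for users who prefer a
  disconnection-native definition; it is not the default because the
  component-restricted form is the direct reading of the formula above.
* **SC** diagonal of `exp(A)` via the symmetric eigendecomposition
  `Σ_k V[i,k]² e^{w_k}`.  Exact to machine precision for the graph sizes in
  scope (dense `eigh`); the walk-series interpretation is used only by the
  test oracle (truncated at l = 60, absolute tolerance 1e-8).
* **EC** principal eigenvector of A: dense symmetric eigendecomposition up
  to 2500 nodes, Lanczos (`eigsh`, fixed all-ones start vector, tolerance
  1e-10) above, with a convergence error that recommends the dense route.
  The sign is fixed by making the largest-magnitude entry positive, then the
  entrywise absolute value is taken and the vector scaled to unit Euclidean
  norm.  On disconnected graphs the score mass concentrates on the component
  with the largest spectral radius; this is the literal definition and is
  logged as a warning rather than silently re-normalized per component.
* **IC** per connected component of size m ≥ 2: `B = D − A + J`,
  `R = B^{-1}`, `IC(i) = m / Σ_{j≠i}(r_ii + r_jj − 2 r_ij)`.  B is strictly
  positive definite on a connected component, so the inversion cannot fail
  on valid input.  The `unscaled` variant omits the factor 2 on the cross
  term, matching some typeset presentations of the formula; both variants
  are verified against independent direct-inversion oracles.  Isolated
  nodes score 0.

Ranking ties are broken by ascending lexicographic gene symbol.  This is a
reproducibility convention, not a scientific claim; equal-scored genes are
interchangeable on the evidence.

## Enrichment

The hypergeometric upper tail `Pr(X ≥ k)` is computed through the survival
function, with a log-space summation fallback for tails below the double
range (and a clamp at the smallest positive float — relevant only beyond
p-scores of ~300, where the score is capped anyway).  The p-score is
`−log10 P`: the decade scale matches the magnitudes conventionally reported
for enrichment results.  Correction across terms is Benjamini–Hochberg by
default (`bonferroni`/`none` options).  The universe defaults to the union
of the annotation collection's gene sets and is user-overridable; published
enrichment numbers produced by web services with unstated backgrounds are
not reproducible desk-side, so no such numbers are asserted anywhere.

## Validation clustering

Samples are clustered by agglomerative hierarchical clustering (SciPy) on
euclidean distances over the signature genes' raw intensities; per-gene
z-scoring is optional and off by default since the method clusters raw
expression intensity.  The default linkage is `average`
(single/complete/ward are exposed and recorded in output metadata); the
dendrogram is cut to exactly k clusters (k = 2 by default, the two-main-
clusters reading).  Association between a 2-cluster assignment and a binary
clinical attribute is tested both ways: Fisher's exact test on the 2×2
table (default) and a one-way F-test on the 0/1 indicator.  Published
clustering p-values for the real microarray dataset could not be
unambiguously reproduced from printed counts under either test, so neither
is treated as a reference value; a generic threshold transform (default
2000 days) dichotomizes time-to-event attributes.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structural* features the method relies on,
at desk scale:

* **Signatures** — 100 sets, sizes log-uniform on [4, 3000] (the published
  collections span orders of magnitude), drawn from a 5000-gene pool; 50
  core genes each enter any signature with probability 0.3, giving the
  recurrent-core / mostly-low-support mixture the filter exploits.
* **Interactome** — 2000 nodes, Barabási–Albert backbone with attachment
  m = 4 (mean degree 8, matching the ~8.9 of real merged interactomes) and
  a planted 40-gene module on the core genes with internal edge probability
  1.0 (a clique, the densest planted structure).  Core genes occupy the
  earliest attachment positions, as curated disease genes tend to be
  well-studied hubs.  Under these defaults all six centralities place ≥ 80%
  of module genes (on average ≥ 89%, BC being the weakest since a clique's
  internal pairs contribute no betweenness) into their top-40 — the
  regression property the tests assert.  It is a property of these shipped
  parameters, not a theorem about arbitrary settings.
* **Expression** — 60 + 60 samples, baseline Normal(8, 1); signature genes
  shifted by 5 (5× the noise sd) in group 2; a binary receptor-status
  analog equal to the group indicator with probability 0.9; numeric outcome
  analogs (age, prognostic-index score, time to metastasis) with
  group-dependent means.

Not emulated: real expression marginals and gene–gene correlation, probe
effects, true interactome degree sequences beyond the hub-heavy tail, and
identifier noise (synonyms, retired symbols).  Passing tests therefore show
the machinery is correct and recovers planted structure under the stated
noise model — not that any particular real signature collection will yield
a biologically superior unified signature.

Determinism: every generator draws from `numpy.random.default_rng` seeded
by (seed, stream-tag); no global random state is touched.  Identical spec
and seed give byte-identical files.

## Degenerate inputs and tie-breaking

Empty networks produce empty score maps; an edge-less network gets all-zero
EC with a warning; k larger than the node count returns all genes with a
warning; clustering merge-distance ties follow SciPy's deterministic
lowest-index rule; a support filter at `min_support = 1` is the identity on
the gene union.

## Problem sizes

The shipped test-and-acceptance configuration uses the default synthetic
scale above (constrained networks of ~2000 nodes), 200 eight-node random
graphs for oracle cross-checks, exhaustive hypergeometric enumeration to
G = 12, 20 replicates for recovery/agreement properties and 200 replicates
for the null-calibration check; the acceptance script reports means over 5
replicates for its recovery quantities.

## Known limitations

Unweighted edges only (confidence-weighted centralities are a natural
extension); no identifier mapping beyond case normalization — users supply
a synonym map if their sources disagree; EC on disconnected graphs reflects
only the dominant component; no survival modelling beyond descriptive
per-cluster summaries.
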