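# Methods

This note records the statistical model, the tunable parameters, the
numerical conventions and the deliberately made design choices behind
`mirpathnet`, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Data model

All statistics operate on log2 feature × sample matrices with a sample
annotation mapping samples to conditions (and optionally to driver-mutation
labels). Matrices are required to be finite and fully annotated at load
time; every downstream contract assumes this. Fold change is defined as the
difference of class mean log2 values — data are already on the log scale,
so no re-exponentiation is performed, and stratified fold changes (case
group restricted to one mutation label) reuse the same operation on a
filtered case group rather than a separate code path.

## Feature filters

Two filters remove uninformative features, combined as a union of removal
sets ("weakly expressed and/or poorly variable"):

* **Weak expression** — per-feature mean below the `drop_fraction` (default
  0.25) empirical quantile of the per-feature mean distribution. The
  quantile uses linear interpolation (the numpy default) and removal is
  strict-below, so tied means at the cutoff survive.
* **Low variability** — Shannon entropy of the profile below 1.4 bits.
  Entropy of a continuous profile is not canonical; the convention here is
  10 equal-width bins spanning the profile's own [min, max], with constant
  profiles defined as H = 0. This keeps the threshold 1.4 well inside
  [0, log2 10] and makes the filter scale-invariant (entropy is invariant
  to affine rescaling of the profile). Whether entropy should be computed
  on linear rather than log2 intensities is unresolved; log2 is used
  because that is the scale of the input matrices.

Both criteria are evaluated on the original matrix, which makes the
composition of the two filters exactly order-insensitive.

## Anticorrelation support

Predicted miRNA→target pairs are tested for expression anticorrelation on
the samples of the comparison at hand. The p-value for Pearson *r* is the
standard two-sided t transform, t = r·√((n−2)/(1−r²)) on n−2 df (|r| = 1
maps to p = 0 by convention). Two-sided p-values with a directional
magnitude filter (r < −0.5) are the conservative default; sidedness of the
original criterion is unknowable from the selection rule alone. The FDR
procedure is Benjamini–Hochberg; the adjusted family is exactly the
predicted pairs that pass the score filter and are measured in both
matrices, so the family is reproducible from the inputs. A pair passes iff
r < −0.5 AND q < 0.1, both strict. The prediction score is treated as an
opaque confidence in [0, 1] with threshold 0.8; a "top fraction of the
score distribution" mode is available as an alternative
(`score_mode="top_fraction"`).

## Pathway model and tests

A pathway is a typed, partially directed graph. miRNA edges always run
miRNA → gene and are repressive in sign semantics; in the probabilistic
model, sign and direction are dropped: the graph is moralized (directed
co-parents married, binding edges kept as plain adjacencies) and min-fill
triangulated with lexicographic tie-breaks, giving a chordal cover with a
junction (clique) tree built as a maximum-weight spanning tree over clique
intersection sizes (Kruskal, deterministic tie-break by sorted clique
labels; the running intersection property holds by the junction-tree
theorem and is verified exhaustively in tests). Pathway nodes missing from
the expression matrix are dropped with a warning before moralization —
imputation would fabricate structure. Disconnected components are joined
into one tree by empty-separator edges; path enumeration treats those edges
as component boundaries, so components are analyzed separately and their
paths pooled.

The Gaussian graphical model MLE constrained to the (chordal) pathway graph
is available in two equivalent forms: iterative proportional scaling over
maximal cliques (`ips_covariance`, the general fitter, convergence declared
when every clique marginal matches the sample covariance within `tol`,
default 1e-8, at most 500 sweeps) and the closed-form clique/separator
formula for decomposable models. The permutation loop uses the closed form,
which is exact on triangulated graphs and orders of magnitude faster; the
test suite checks the two agree to 1e-6.

Two statistics compare classes under the model, with MLE (1/n) covariance
estimates:

* **variance**: T_v = n·log det Σ̂_pooled − n₁·log det Σ̂₁ − n₂·log det Σ̂₂,
  the log-likelihood ratio of class-specific GGM fits against the pooled
  fit (sensitive to changes in relation strength);
* **mean**: T_m = (n₁n₂/n) · d′ K̂_pooled d, a Hotelling-type quadratic form
  of the class mean difference weighted by the pooled GGM concentration.

Null distributions come from permuting class labels. One permutation stream
(seeded `numpy` Generator) drives both statistics and all clique-level
statistics of a pathway, and p-values use the add-one estimator
p = (1 + #{perm ≥ obs}) / (1 + n_perm), so p ≥ 1/(1+n_perm) by
construction. Whether the original formulation used asymptotic rather than
permutation nulls is not documented; permutation nulls were chosen because
they are exact under exchangeability and make no clique-size asymptotics.
Clique-level tests use the saturated model within each clique. Degenerate
(non-positive-definite) clique covariances raise rather than being ridged.

Across pathways, the mean-test and variance-test p-value families are
BH-adjusted separately, and a pathway is significant when
min(q_mean, q_var) ≤ 0.1 — significance on *either* test, the inclusive
reading; an "AND" mode is a configuration switch.

## Path scoring, meta-pathway, final selection

Paths are simple clique-tree paths between pairs of leaf cliques
(single-clique components yield their trivial path). A path's score is the
mean over its cliques of −log₁₀ min(p_mean, p_var); the mean (rather than
sum) avoids rewarding length per se. The top 10 paths ranked across all
significant pathways (ties broken by pathway id, then path label) are
merged — union of node sets plus all edges of the augmented source graphs
induced on that union — into the meta-pathway, which is re-analyzed from
scratch (moralize → triangulate → clique tree → clique tests → scoring).
Paths at or above the 75th percentile (linear interpolation) of the final
score distribution are reported, ties kept. "Top 10 overall" rather than
per pathway is a choice (configurable via `top_k_paths`); at permutation
floor saturation many paths tie, and keeping ties at the final quartile
guards against arbitrary truncation there.

## Circuits

Candidate TF–miRNA–gene triangles are exact joins of the catalogs and the
score-filtered prediction table, restricted to measured features, with the
regulated gene never the TF itself. Retention requires all three pairwise
|r| ≥ 0.5 (non-strict), computed on the same sample subset as the
comparison being analyzed. TF→miRNA and TF→gene catalog relations are
unsigned; their effective sign is taken from the observed correlation.
miRNA→target edges are treated as repressive for coherence classification
regardless of the observed sign — mechanism-faithful, with the observed r
reported alongside. A loop is coherent when the direct edge's sign equals
the product of the signs along the indirect two-step route; for the
TF-master topology this reduces to sign(r_TF,gene) = −sign(r_TF,miRNA), for
the miRNA-master topology to r_TF,gene > 0. Circuits are attached to the
final network only when they share at least one member with it.

## Network assembly

Merging is union on node id and (src, dst, edge-type) with provenance sets
unioned; a gene catalogued as a TF is typed `tf` (one node, promoted —
gene/miRNA conflicts are errors). Fold-change slots are named by comparison
label from the configuration, not hard-coded to any study's condition
names. Missing fold changes stay absent, never zero. GraphML and JSON
round-trip exactly; SIF is topology-only. All orderings in exports are
sorted, so reruns with the same seed are byte-identical.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the scale of a modest two-tissue case/control expression study:

* three classes (case, two control classes; 30 samples each) so the
  two-comparison merge logic is exercised; case samples carry cyclic
  driver-mutation labels for the stratified fold-change path;
* 300 genes and 40 miRNAs, baseline log2 values Normal(μ_f, σ) with
  per-feature means uniform in [4, 12] and σ = 1;
* three 25-node pathways over disjoint gene blocks, each a cascade tree
  with a few cross edges; the first pathway contains a planted 5-gene chain
  whose case-class means are shifted by +1.5 σ. The scaffold hangs off the
  chain's middle node, leaving the chain ends terminal, so the planted
  cascade is itself a leaf-to-leaf path — the structure the path statistic
  is designed to localize;
* 10 miRNA–target pairs planted as bivariate normal with ρ = −0.8 (the
  count is a generator parameter; the pairing is injected pairwise, exactly
  what the selection statistic tests, not a full regulatory simulation).
  Targets are pathway genes off the planted path, so the sample correlation
  of a planted pair follows the plain Fisher-z interval, uncontaminated by
  the mean shift;
* two feed-forward circuits per topology built from a latent driver t with
  loadings ±0.85 (pairwise |ρ| ≈ 0.72), sign patterns chosen to yield one
  coherent and one incoherent loop per topology. Circuit members are drawn
  from genes outside the pathways so the planted effects stay orthogonal;
  consequently planted circuits do not link to the path-derived network,
  and linking is exercised by unit tests rather than by the bundle;
* a prediction table containing all planted pairs (scores ≥ 0.8) plus 60
  decoy pairs, half of them above the score threshold so the FDR machinery
  is exercised on truly null tested pairs; every other planted pair is also
  catalogued as validated, exercising the validated-over-predicted edge
  precedence; two additional miRNAs are catalogued as validated regulators
  of planted path genes (no correlation planted — validated targeting need
  not show anticorrelation in a given tissue), which carries miRNA nodes
  into the deregulated paths;
* planted regulator miRNAs get baseline means in [8, 12]: an unexpressed
  miRNA cannot regulate, and the weak-expression filter would censor it by
  construction otherwise.

Recovery is scored as precision/recall on id sets per component. For the
final-path component, the caller scores gene nodes: the planted truth of
that component is a gene path, and miRNA attachment is scored by the
supported-interaction component. Circuit recovery is scored on the
discovered (scored and filtered) circuit list, before network linking,
because linking depends on which paths happen to be selected and is a
reporting join rather than part of discovery.

What the generator does *not* emulate: array-level probe noise, batch
effects, correlated gene-gene background structure within pathways (the
scaffold genes are independent given the planted effects), realistic
pathway overlap, or miRNAs with many targets. Passing recovery tests
therefore demonstrates the statistical machinery is correct and calibrated
under its own assumptions, not that effect sizes of real studies are
detectable.

## Problem sizes and numerical conventions

Default test and acceptance runs use 500 permutations for recovery runs and
199 for null-calibration replicates, 50 null bundles in the acceptance
suite and 20 in the acceptance script — sizes chosen so the whole pipeline
(including the two-comparison run) completes in seconds while keeping
permutation granularity (1/200) well below the 0.1 decision thresholds.
Seeds: every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from the configured seed via `numpy.random.SeedSequence`,
so independent stages have independent streams yet the whole run is
reproducible byte-for-byte. All tie-breaks (elimination order, clique
labels, path ranking, export ordering) are lexicographic.

## Known limitations

* Pathway input is a neutral edge-list dialect; KGML/BioPAX importers are
  out of scope, as are compound/group nodes of curated pathway databases.
* The clique-level saturated tests ignore between-clique structure; a
  strong signal in a large clique can dominate paths through it
  (permutation-floor saturation), which the tie-keeping final selection
  mitigates but does not remove — raise `n_perm` to separate tied paths.
* The variance statistic requires every clique smaller than the smallest
  class; very dense pathways with few samples will raise on degenerate
  covariances rather than regularize.
* FDR families are per comparison; a global family across comparisons
  would be stricter.
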