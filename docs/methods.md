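# Methods

## The model

The package searches a molecular interaction network for *ego-network
modules*: a focal gene (the ego) together with every gene within graph
distance *k* of it.  The premise is that a disease process perturbs a
neighbourhood of interacting genes collectively, so a gene set drawn from a
network neighbourhood can predict a binary phenotype even when no single
member is differentially expressed on its own.

For every node with degree ≥ 2 the module is grown outward level by level
(snowball sampling).  At each level the member genes' expression is scored by
the stratified cross-validated accuracy of a classifier — the module score
S_i — and growth stops at the first level whose score is *strictly* lower
than the previous level's (a tie continues growth, since only a drop is
evidence that the added shell dilutes the signal).  The reported module is
the level with the maximal score in the trace, the earliest on ties.

Module significance is assessed by permuting the phenotype labels B times and
rescoring the same gene set; the add-one estimate
p = (1 + #{null ≥ observed}) / (B + 1) never returns zero and is valid for
any B.  Within each retained module, per-gene node importance V_ij is the
out-of-bag permutation importance of a random forest fitted on the module's
genes: for each tree t with out-of-bag sample OOB_t and misclassification
rate errOOB_t, gene j's values are permuted within OOB_t and the importance
is the mean over trees of the error increase.  Labels are binary and coded
0/1, so the misclassification rate is used as the error; for 0/1 targets
under majority-vote prediction it coincides with the mean squared error that
regression-forest formulations of this importance use.  Finally, genes are
ranked globally by

    M_j = Σ_i S_i · V_ij

summed over the retained modules (V_ij = 0 when gene j is not a member), so
a gene accrues rank from every high-scoring module it belongs to — hubs that
sit in many predictive neighbourhoods rise, including hubs that are not
themselves differentially expressed.  Differential expression is flagged
separately by a per-gene two-tailed Welch t-test with Benjamini–Hochberg
adjustment, purely as an annotation on the ranking.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `classifier` | `svm` | RBF-kernel SVC, C = 1, `gamma="scale"`. The cubic outcome in the benchmark is non-linear, which a linear kernel handles poorly; the scale rule adapts the kernel width to the standardised features. `knn` (k = 5, Euclidean) and `rf` (500 trees) are the alternatives. |
| `folds` | 5 | Stratified CV; stratification guarantees both classes in every fold. Must not exceed the smaller class size. |
| `max_level` | 3 | Levels beyond 2 are rarely chosen in practice on scale-free graphs (the drop rule fires earlier); the cap bounds cost on hub egos. |
| `node_cap` | 300 | A hub's level-2 shell in a scale-free graph can engulf the network; growth stops before a level that would exceed the cap. Chosen for networks of a few hundred to a few thousand nodes; scale it proportionally for much smaller graphs. |
| `score_cutoff` | 0.9 | Accuracy a module must reach to be retained and to contribute to M_j. |
| `n_permutations` (B) | 1000 | Permutations for the module p-value (p ≥ 1/1001). |
| `importance_trees` (T) | 500 | Trees in the importance forest; V_ij estimates stabilise well below this for module-sized gene sets. |
| `de_fdr` | 0.05 | BH-adjusted threshold for the DE annotation. |

Per-fold standardisation (training-fold mean/sd applied to the held-out
fold) makes the score invariant to affine rescaling of any gene and avoids
information leak from the test fold.  A constant training-fold feature is
centred only.

The aggregated-Z baseline scores a gene set by the mutual information (bits)
between the class labels and the per-sample mean of member z-scores,
discretised into 8 equal-width bins, and grows a subnetwork greedily from a
seed while the MI strictly improves.  The bin count is a fixed plug-in
choice; the baseline exists for method comparison, not for inference, so any
fixed estimator serves.

## The synthetic benchmark

`generate_instance` emulates the structure of a PPI-plus-expression study:

* a preferential-attachment (Barabási–Albert, m = 3) graph of 500 nodes —
  scale-free degree distribution, connected, simple, no self-loops;
* i.i.d. standard-normal expression for 500 genes × 100 samples;
* a true ego drawn uniformly among nodes of degree 5–20; its level-1
  ego-network is the planted module; 80% of the members (rounded) are marked
  disease genes — the ego is forced into the disease set in the
  `ego_associated` scenario and out of it in `ego_excluded`;
* per-sample outcome Y = Σ X_i (linear) or Σ X_i³ (cubic) over the disease
  genes, dichotomised to label 1 iff Y ≥ 0.

m = 3 gives 500-node graphs a reliable supply of degree-5–20 candidate egos.
Recovery is "any of the top-k modules has Jaccard ≥ 0.5 with the planted
member set"; capturing the true ego is reported as a secondary criterion.
Per-instance seeds derive from `SeedSequence([master_seed, index])` so any
single instance can be replayed in isolation.

What the generator does *not* emulate: correlated co-expression within
modules, batch or technical noise, unbalanced class sizes, measurement-scale
effects, or any biological edge semantics.  Passing benchmarks therefore
demonstrate that the search, scoring and ranking machinery behave as
specified under a clean additive/cubic signal — not that the method will
attain similar recovery on real cohorts.

## Desk-scale study sizes

The validation studies in `egonet.studies` reduce problem sizes so the whole
battery runs on one CPU in minutes; distributional conditions are never
changed.

* SVM recovery study: 200-node networks, 30 instances per outcome model,
  5-fold CV — recovery percentages are compared to the reference rates
  (68/53 top-1, 89/83 top-5) within two binomial standard errors at n = 30.
* SVM-vs-RF direction study: 50-node networks, 50 paired instances, cubic
  outcome, top-1 only, 3-fold CV, RF reduced to 25 trees, node cap 30
  (proportional to the default 300 at 500 nodes).  A random forest costs
  roughly a millisecond per tree per fold on instances of this size, which
  makes full-scale RF enumeration disproportionate to what a direction
  comparison needs; the reduced forest makes RF's module scores noisier,
  which works against RF, but the assertion is a direction, not a magnitude.
* Method comparison: 100-node networks, 30 instances, linear outcome,
  `ego_excluded` scenario — the setting in which seed-centred greedy search
  is structurally handicapped at including the uninformative ego, while the
  ego-network definition includes the ego by construction.

## Numerical and degenerate-input choices

* Stopping comparison is strict (`<`); tie-breaks everywhere are
  deterministic (lexicographic gene/ego identifiers, smaller module first in
  ranking) so repeated runs are byte-identical.
* Zero-variance genes: contribute zero z-scores to the baseline activity
  (logged); centred only in CV standardisation; p = 1 in the t-test when
  both classes are degenerate.
* Modules with fewer than two genes present in the expression data are
  skipped with a logged reason rather than scored.
* Genes absent from the expression matrix (or nodes absent from the network)
  are dropped by `align` before discovery; imputation is out of scope.
* Duplicate expression rows are an error — silent averaging could hide an
  identifier-mapping problem.
* The permutation p-value and the importance permutations use
  `numpy.random.default_rng(seed)`; sklearn components receive derived
  integer seeds, so identical configuration + seed reproduces every number
  exactly.

## Known limitations

* Binary phenotypes only; no multi-class, continuous or survival outcomes.
* No hyperparameter tuning or nested CV — S_i is a comparative score, not an
  unbiased estimate of generalisation accuracy (all modules are scored with
  the same protocol, so the comparison is fair, but the absolute values are
  optimistic for the selected top modules).
* Modules overlap heavily by construction (neighbouring egos share most
  members); no redundancy removal is attempted.
* p-values are reported raw across modules; BH across modules is available
  but not the default.
* The score is fold-granular (multiples of 1/n per fold), so ties are common
  on small sample sizes; the deterministic tie-breaks make results
  reproducible but the ordering within a tie is not statistically meaningful.
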