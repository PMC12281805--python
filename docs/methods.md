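# Methods

This note documents the models, estimators and design choices behind the
package: what is computed, under which assumptions, and what the
synthetic test suite does and does not demonstrate.

## Problem setting

Molecular machine-learning datasets pair a feature representation of
each molecule (binary substructure fingerprints, hand-crafted
descriptors, or learned embeddings) with a scalar property such as a
binding affinity. How well a regressor generalizes on such a dataset
depends jointly on the property landscape (how smoothly the label varies
with structural similarity) and on the geometry of the representation's
feature space. The package quantifies that geometry with persistent
homology and intrinsic-dimension estimates, computes classical
landscape-roughness baselines, benchmarks regressors across
representations, and fits a meta-model that predicts normalized
generalization error from the topological descriptors alone.

## Vietoris–Rips persistent homology

Given an n-point cloud and a metric (Euclidean, Manhattan, cosine, or
Jaccard for bit vectors; the Tanimoto similarity is 1 − Jaccard
distance), the Vietoris–Rips filtration is the nested family of clique
complexes over the ε-neighborhood graphs as ε grows. Homological
dimensions 0 (connected components) and 1 (independent cycles) are
tracked; each feature is a (birth, death) interval.

Implementation:

* **Dimension 0** via the minimum spanning tree: the sorted MST edge
  weights are exactly the merge (death) times, so a full filtration has
  exactly n − 1 finite bars, all born at 0. scipy's MST treats zero
  entries of a dense matrix as absent edges, so all weights are shifted
  by a constant (MST-invariant) before extraction; duplicate points
  therefore keep their zero-length merge edges, which are then dropped
  as zero-persistence intervals.
* **Dimension 1** via mod-2 column reduction of the clique 2-skeleton
  boundary, executed in the anti-transposed (persistent-cohomology)
  order with clearing: columns are edges in reverse filtration order,
  rows their cofacet triangles, and the columns of edges that are
  negative in dimension 0 (the Kruskal edges under the same tie-break
  order) are skipped, since they must reduce to zero. This avoids
  grinding millions of positive triangle columns to zero and reduces a
  300-point cloud in well under a second. Edges and triangles are
  pruned at the enclosing radius (min over vertices of max distance),
  beyond which the complex is a cone and no finite dimension-1 interval
  can exist.
* A deliberately naive full boundary-matrix reduction over all
  simplices of dimension ≤ 2 (`topolearn.reference`) serves as an
  independent cross-check; the fast path must agree with it exactly on
  random clouds, and this equivalence is asserted in the test suite on
  Euclidean and Jaccard inputs.

Conventions: mod-2 coefficients; ties in filtration values broken by
lexicographic vertex order (stable sorts over deterministic
enumerations); zero-length intervals discarded; infinite intervals
(including the single essential component bar) removed at finalization;
no distance threshold by default.

## Diagram descriptors

Per homological dimension i ∈ {0, 1}: the Betti number (count of finite
intervals) and its per-point normalization; min/max/avg/std/sum of the
lifetimes Δ = d − b and midlives μ = (b + d)/2; the same aggregators of
the sum-normalized lifetimes p = Δ/ΣΔ and midlives ν = μ/Σμ; and the
persistence entropy E = −Σ p log p with the natural logarithm (entropy
is maximal, log β, exactly when all lifetimes are equal). The standard
deviation is the population form, so it is defined (0) for a single
interval. Raw and normalized statistic families are distinct named
columns (`lifetime_*` vs `lifetime_norm_*`). A dimension with no
intervals — common for small clouds in dimension 1 — propagates NaN, a
deliberate "no signal" marker handled downstream, never silently 0.
Normalized descriptors, Betti numbers and entropy are invariant to
uniform rescaling of the metric.

## Intrinsic dimension

* **PH-dimension**: subsamples of size s ∈ {100, 150, …, 2000} ∩ [1, n]
  (one seeded draw per size by default, ≥ 4 sizes required) give total
  persistence E^α = Σ Δ^α; the OLS slope m of log E^α on log s yields
  the estimate α/(1 − m) with α = 1. For an intrinsically d-dimensional
  cloud the total dimension-0 persistence grows like s^((d−1)/d), so the
  estimator recovers d. Slope m ≥ 1 or zero persistence (duplicate-only
  clouds) is reported as NaN with diagnostics rather than a spurious
  number.
* **TwoNN**: per point the ratio μ = r2/r1 of the two nearest-neighbor
  distances follows a Pareto law with shape equal to the intrinsic
  dimension on a locally uniform manifold. The estimate is the slope
  through the origin of −log(1 − F(μ)) on log μ over the empirical CDF,
  after discarding the largest 10% of ratios (the customary guard
  against heavy-tail noise). Duplicate rows make r1 = 0 and are a hard
  error naming the offending rows.
* **Local PCA**: per point, eigenvalues of the covariance of its k = 100
  (capped at n − 1) nearest neighbors are counted above 0.05 times the
  leading eigenvalue; the estimate is the mean count. On a noiseless
  linear manifold the count is exact (rank). The per-neighborhood
  average (rather than one global PCA) is the intended local variant;
  the eigenvalue-ratio threshold follows the conventional
  Fukunaga–Olsen prescription.

## Landscape roughness baselines

* **SALI**: |ΔA| / (1 − sim) per pair. Pairs at sim = 1 (duplicates
  under the chosen similarity) are masked and counted rather than
  emitted as NaN; summaries (mean, max) run over unmasked pairs.
  Default similarity: Tanimoto for binary features, 1/(1 + Euclidean)
  otherwise.
* **SARI** = ½(score_cont + (1 − score_disc)). The raw continuity score
  is the potency-difference-weighted mean similarity over pairs below
  the similarity threshold (0.65); the raw discontinuity score is the
  mean |ΔA| over pairs at or above it. Raw scores are min–max
  normalized within the batch of datasets being compared (no external
  reference panel exists here); for a batch of one the continuity score
  is used as-is (it is already a weighted mean of similarities in
  [0, 1]) and the discontinuity score is divided by the label range.
  The ½(· + ·) form keeps the index in [0, 1].
* **RMODI**: RI_i = |y_i − y_NN(i)| / range(y) − τ with tolerance
  τ = 0.1; RMODI is the fraction of molecules with RI_i < 0. Constant
  labels define RMODI = 1 (every neighborhood trivially smooth) with a
  warning. The sign-threshold construction reproduces the defining
  property of the rivality index — negative exactly when the nearest
  neighbor's activity is similar — with a single explicit tolerance.
* **ROGI** = ∫₀¹ 2(σ0 − σt) dt. Complete-linkage clustering of the
  (max-normalized, for the classic variant) distance matrix; at each
  threshold every label is replaced by its cluster mean and σt is the
  population standard deviation of the coarse-grained vector — i.e. the
  square root of the between-cluster variance, updated incrementally
  along the merge sequence. The classic variant evaluates a 51-point
  even grid of thresholds; the xd variant instead places the k-cluster
  partition at t = 1 − (k − 1)/(n − 1), which removes the direct
  dependence of the threshold scale on representation dimensionality.
  Both integrals use the trapezoid rule; labels enter on their native
  scale, so constant labels give exactly 0.

## Benchmarking and error normalization

Each configuration (dataset, representation, sample size, split scheme,
model family) is evaluated with a single seeded 80/20 holdout; on the
training side a 5-fold grid-search CV (RMSE criterion) selects
hyperparameters from desk-scale grids — random forest: ensemble size
{100, 500} × depth {unlimited, 10}; neural network: hidden widths
{(64,), (128, 64)} × weight decay {1e−4, 1e−3} with early stopping.
Group splits assign whole groups (e.g. scaffold identifiers, supplied
as a column, never computed here) to one side; leakage is asserted in
tests. Raw RMSE/MAE are min–max normalized within each dataset so that
the best representation maps to 0 and the worst to 1; ties normalize to
0 with a warning. Label standardization is off by default; descriptors
are computed on all data by default (a train-only flag exists).

## The meta-model

Run records are joined with their configuration's descriptor vector
(key: dataset, representation, sample size). Feature set `PH` holds
persistence descriptors and dimension estimates only; `C` adds controls
(sample size, dimensionality, metric/model/split one-hots,
hyperparameters) and is used for confound analysis only — the
deployable predictor is `PH`, since controls are unavailable when
scoring a new representation. Missing descriptor values are encoded for
the forest as a sentinel one unit below the per-feature training
minimum plus a missing-indicator column, fitted per training fold so no
holdout statistics leak. The regressor is a random forest tuned over
{300 trees} × depth {unlimited, 12} × min-leaf {1, 5} by internal
5-fold CV, and predictions are clipped to [0, 1], the range of the
normalized error. Correlation screens report per-feature Pearson and
Spearman coefficients with two-tailed p-values (t-transform), pairwise
NaN dropping, and no multiple-testing correction. Feature importances
are impurity-based and renormalized to sum to 1; fold importances are
averaged.

The permutation null for the CV correlations shuffles targets *within
each dataset*. The normalized error is a within-dataset min–max
quantity — values are only comparable inside their dataset — so the
exchangeable unit under the null hypothesis ("descriptors carry no
information about which configuration of a dataset errs more") is the
row within its dataset. A global shuffle would additionally perturb
per-fold target means and inject the well-known leave-group-out
regression-to-the-mean artifact: even a perfect implementation then
shows an expected aggregated correlation of about −1/√m for folds of m
rows, which at desk scale (m ≈ 8–30) is far from zero. The
within-dataset shuffle preserves every fold's target distribution and
gives an unbiased null.

## Synthetic data: what it emulates and what it does not

Point-cloud generators (circle, sphere, hypercube(d), Gaussian blobs,
line, Bernoulli bit matrices) provide known topology and intrinsic
dimension. Landscapes place a smooth radial sinusoid sin(ω·‖x − x̄‖)
with ω = 2 (hence Lipschitz constant 2 in the feature metric) over a
cloud; planted activity cliffs replace a seeded fraction of labels with
the base value plus an offset of 3× the smooth label range, so a
cliffed point adjacent to a smooth one violates any smoothness bound by
construction. Group identifiers come from seeded spatial k-means, one
group per ~30 points.

The planted meta-benchmark generates datasets (Gaussian-blob clouds
with varying blob count and label noise, no label cliffs) ×
representations (seeded linear embeddings of the latent coordinates
with increasing additive coordinate noise). The noise level is the
planted roughness axis: distorting the feature space scrambles
neighborhoods, which is precisely what an activity cliff is in a given
representation — the labels are representation-independent, so
roughness that the descriptors can see must live in the feature
geometry. Measured on the default grid, RMODI falls from ~0.7 to ~0.2
and raw RMSE roughly triples across the distortion levels. Default
scale: 4 datasets × 6 representations × sample sizes
{100, 150, 200, 250, 300}, forest family, reduced grid {100 trees} ×
depth {unlimited, 10}; PH-dimension is computed for dimension 0 only at
this scale. The size schedule follows the spirit of a multi-size
sampling design while keeping a full run in minutes; having ~30 rows
per held-out dataset also keeps the leave-one-dataset-out
regression-to-the-mean artifact (expected fold correlation −1/√m under
a null target) well below the planted signal.

What passing these tests does **not** show: real fingerprints are not
i.i.d. Bernoulli bits, real embeddings are not noisy linear maps of a
3-D latent space, and real activity cliffs are not constant-offset
outliers; absolute descriptor values and meta-model accuracies on real
corpora will differ. The synthetic suite demonstrates correctness of
the machinery and recoverability of a planted geometry–error link, not
chemical realism.

## Numerical choices and degenerate inputs

* Distances: scipy `pdist`; exact symmetry enforced; Jaccard between
  two all-zero rows is 0 (identical empty substructure sets), logged.
* Filtration tie-breaks: stable sorts over lexicographic enumerations.
* OLS fits use `np.polyfit` (PH-dim) and the closed-form
  through-origin slope (TwoNN).
* Degenerate cases yield NaN + diagnostics (zero persistence, slope
  ≥ 1, constant covariance), defined constants with warnings
  (RMODI = 1 and ROGI = 0 for constant labels, E_rel = 0 for tied error
  batches), or typed errors (duplicate rows for TwoNN, infeasible group
  splits, metric/representation mismatch).

## Known limitations

* Homological dimension ≥ 2, sparse/approximate filtrations and alpha
  complexes are out of scope; the reduction is exact, not approximate.
* The dimension-1 reduction materializes all triangles below the
  enclosing radius; clouds beyond ~1000 points become slow and are
  better subsampled (as the PH-dimension estimator already does).
* SARI's batch normalization makes its absolute value
  batch-dependent; only orderings within a batch are meaningful.
* The meta-model's leave-one-representation-out transfer is weaker than
  leave-one-dataset-out on the synthetic grid: a held-out distortion
  level is genuinely out of distribution for a 4-point training grid.
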