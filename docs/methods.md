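# Methods

## Problem setting

`lactosense` predicts real-valued sensory phenotypes of fermented milk —
electronic-tongue taste channels (Sourness … Saltiness) and electronic-nose
sensor responses (W1C … W3S) — from binary genomic feature matrices of the
fermenting *Lactococcus lactis* strain.  The genotype space concatenates
three feature classes produced by standard pan-genome tooling: SNP calls,
gene presence/absence, and intergenic-region (IGR) variants.  The regime is
extreme p ≫ n (order 10⁵ features, order 10² strains), so the method is
dominated by feature selection.

## The selection pipeline

Each phenotype is processed independently by a serialized four-stage
pipeline:

1. **Variance threshold (VT).**  Features with population variance strictly
   below a cutoff t are removed.  The filter operates on raw 0/1 values,
   where a Bernoulli(p) feature has variance p(1−p); the tuning range for t
   is [0, 10⁻⁴], i.e. the filter only prunes (near-)constant features.
2. **Univariate F selection (UFS).**  Each feature j is scored by the simple
   regression F statistic F_j = r_j²(n−2)/(1−r_j²), r_j being the Pearson
   correlation with the target.  The top `percentile` percent by score are
   kept (count `ceil(p·percentile/100)`), ties resolved toward the lower
   feature index; a perfectly correlated feature scores +∞ and a constant
   feature 0.
3. **RFECV.**  A ridge (L2) estimator with fixed strength α = 1 is fitted on
   standardized features; each round eliminates the `step` features with the
   smallest |coefficient|, never dropping below `min_features_to_select`.
   The mean shuffled 10-fold CV score (choice of R², or negated MSE / RMSE /
   MAE) is recorded at every visited feature count, and the count with the
   best mean score wins; ties go to the smaller count (parsimony).
4. **PCA.**  The standardized survivors are projected onto the top
   `n_components` principal directions (full SVD, mean-centered, orthonormal
   loadings); a ridge model (α = 1) on the component scores is the final
   predictor.

### Numerical implementation of RFECV

The elimination loop works in the kernel dual.  With Z the standardized
survivor matrix and M = (ZZᵀ + αI)⁻¹, the held-out residuals of a ridge fit
trained without fold T are exactly e_T = M_TT⁻¹(My)_T (the block
generalization of the leave-one-out shortcut), so the per-count CV score
needs only fold-sized solves from one n × n matrix.  When columns are
eliminated the Gram matrix is downdated and M is updated by the Woodbury
identity, with a full re-inversion every 64 rounds to bound accumulated
drift.  The RFECV-internal estimator is therefore ridge *without intercept*
on globally standardized features and a globally centered target; a unit
test verifies the shortcut against direct per-fold `sklearn` ridge fits to
machine precision.  Elimination ties (equal |coefficient|) drop the
lower-index feature first.

Stage failures (empty VT survivor set, fewer features than the RFECV floor,
PCA dimension exceeding survivors or n−1, degenerate target) surface as
named errors when fitting directly, and as fitness −∞ inside the search.

## The Dung Beetle Optimizer

Pipeline parameters (threshold, percentile, step, min features, scoring
criterion, PCA dimension) are tuned by a Dung Beetle Optimizer: population
50 split 20%/40%/20%/20% into rolling / foraging / stealing / reproducing
beetles, stopping after 100 iterations (reduced budgets are used at desk
scale; the tests state theirs explicitly).  Update rules follow the original
algorithm: ball-rolling x ← x + αk·x_prev + b·|x − X_worst| with a random
defection sign α ∈ {±1}; a tangent "dance" x ← x + tanθ·|x − x_prev| with
probability 0.1 (θ uniform on (0,π), a vertical angle leaves the beetle in
place); brood balls resampled inside the region X*·(1∓R) around the
current-iteration best with R = 1 − t/T, clamped to that region; foragers
x ← x + C₁(x − Lbᵇ) + C₂(x − Ubᵇ) around the global best's shrinking region,
C₁ ~ N(0,1), C₂ ~ U(0,1) per dimension; thieves x ← X_best +
S·g·(|x − X*| + |x − X_best|), g ~ N(0,1).  Constants k = 0.1, b = 0.3,
S = 0.5.  Role membership is a static index block; local best = best of the
current population, global best = incumbent.  For centers with negative
coordinates the multiplicative region bounds are sorted elementwise before
clamping, which reduces to the textbook formula on positive domains.

The population is continuous; positions are decoded at evaluation time
(integers rounded half-up, categorical dimensions floored into their index
range).  Because decoding is many-to-one, fitness values are cached on the
decoded point; additionally the RFECV mask — the expensive part — is cached
on its own sub-key that excludes the PCA dimension, and the VT mask is keyed
by its survivor count (the threshold is compared against a single variance
vector, so the count determines the mask).  Per-feature F statistics are
computed once per search: a feature's F does not depend on which other
features survive.

The fitness is the 10-fold CV score of the final ridge on component scores,
**using the candidate's own scoring parameter** (error metrics negated).
One consequence worth knowing: fitness values are not commensurable across
scoring categories (an R² near 1 numerically dominates a negated MSE), so
the search tends to settle in R²-scored regions of the space.  This is the
specified behaviour of the tuned objective, kept as-is.

Search-space defaults: threshold [0, 10⁻⁴], percentile [1, 100], step
[1, 10], min features [100, 300], scoring {R², MSE, RMSE, MAE}, PCA
dimension [1, min(n−1, 100)] — the upper cap keeps every decoded point
feasible after an RFECV floor of ≥ 100 survivors.  Whether the DBO-internal
CV folds coincide with the final evaluation folds is an open choice; the
implementation shares one fold seed between them.

## Model comparison and importance

Ten regression families (ridge, lasso, elastic net, SVR, k-NN, decision
tree, random forest, gradient boosting, XGBoost, and a one-hidden-layer
64-unit MLP) are compared on the component scores under shuffled 10-fold
CV; R², MAE, MSE, RMSE are averaged over folds (fold-mean convention, not
pooled predictions) and the best mean R² wins, ties resolved to the
lexicographically first name.  Hyperparameters are library defaults frozen
in a registry; boosted ensembles use 100 estimators.

Feature importance back-projects the final ridge through the PCA loadings:
c = Lβ, the exact gradient of the prediction with respect to the
standardized selected features, retaining sign.  Contributions are reported
unnormalized on the standardized-feature scale and ranked by |c| with ties
by feature id.

Shared features between two phenotypes are counted at the post-RFECV stage
(the last stage at which survivors are original features), and the
overlap/correlation association is the Spearman ρ between |pairwise
phenotype correlation| and shared count over all unordered pairs.

## Synthetic data generator

The generator emulates the statistical skeleton of a strain panel:

* features are i.i.d. Bernoulli(p_j) with p_j ~ U(0.1, 0.9) per feature
  (accessory-genome frequencies span a wide range; probabilities strictly
  inside (0,1) keep every feature informative), split into SNP/GENE/IGR
  blocks with class-prefixed ids;
* each phenotype is a sparse linear combination of planted causal features
  (default 20) with effect magnitudes U(0.5, 1.5) and random signs, plus
  Gaussian noise; every causal feature carries a single signed weight shared
  by all phenotypes containing it, so planted causal overlap translates into
  phenotype correlation (independently re-drawn signs would cancel it);
* noise is parameterized by the target signal fraction
  Var(signal)/Var(y) (default 0.9, the high-R² regime the method operates
  in), resolved from the empirical signal variance;
* causal-set overlap between phenotype pairs is planted exactly via disjoint
  shared pools, producing the correlation gradient the shared-feature
  analysis studies.  The default eight-channel design pairs phenotypes at
  75% / 25% / 0% overlap; a four-phenotype design plants overlaps
  {0, 10, 30}.

Defaults are 194 samples and (107,661, 49,146, 29,301) features per class —
the scale of the real panel — while tests and the acceptance script use
smaller feature spaces and state their sizes.

What the generator deliberately omits: linkage structure (features are
independent, so causal-recovery metrics are unambiguous but the redundancy
patterns of real pan-genomes are absent), population structure among
strains, non-additive (epistatic) effects, and measurement drift in the
sensor arrays.  Passing tests therefore demonstrate that the machinery
recovers planted additive sparse signal and reproduces the qualitative
overlap/correlation direction — not that real genomes satisfy those
assumptions.

## Reproducibility and scale choices

All randomness flows from integer seeds through `numpy` seed sequences; the
same seed reproduces matrices, searches, folds, and CLI artifacts
bit-identically (manifests record seeds and a config hash, not timestamps).
The acceptance script runs the planted-recovery study at n = 200 with 2,000
features and DBO budget pop 8 × 12 iterations over 3 seeds, and the
overlap-trend study with 600 features over 3 seeds — sizes chosen as the
package's desk-scale defaults; the test suite's planted-recovery check uses
5,000 features with pop 10 × 20 iterations over 5 seeds.

## Known limitations

* The PCA stage is unsupervised: it retains directions of high feature
  variance, not of predictive value, and the component count is constrained
  below the survivor count.  When the component count is far below the
  number of survivors, part of the causal signal is necessarily discarded
  (on standardized near-isotropic features, roughly in proportion to the
  dropped dimension fraction); the parameter search compensates by favouring
  larger component counts.  Relatedly, a loose univariate percentile can
  *hurt* downstream CV by concentrating spurious in-sample correlators; the
  stage-wise gain curve none ≤ UFS ≤ RFECV holds when the percentile is
  tight enough to enrich true signal.
* The fitness's dependence on the candidate's own scoring parameter (above)
  makes the scoring dimension partly self-selecting.
* PCA is fitted on all samples before the final CV (component scores are
  in-sample), matching the serialized pipeline design; reported CV R² is
  therefore optimistic relative to a fully nested evaluation.
* Ridge strength is fixed at 1.0 throughout rather than tuned.
* Standardization statistics are computed on the full sample, including
  inside the RFECV CV (a deliberate, documented simplification).
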