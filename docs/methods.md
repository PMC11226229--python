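# Methods

## Metrics

All analyses operate on a response matrix `X` (rows = conditions, columns
= features/units) plus a design table mapping each condition either to
(base scene, varied parameter, level) — *augmentation mode* — or to a
class label — *grouped mode*, for datasets in which identity and nuisance
variables co-vary and only class membership is known.

**Variance convention.** "Variance" always means the trace of the
feature-space covariance (variance summed over features) with the *n*
denominator. The choice of denominator cancels in every ratio-based score
but is applied consistently so intermediate quantities are comparable.
One consequence worth knowing: the per-scene sample variance over L
levels underestimates the generating latent variance by the factor
(1 − 1/L); both the numerator and denominator of each factorization score
carry the same factor, so the scores themselves are unbiased in this
respect.

**Parameter-induced variance** (augmentation mode) is the total variance
of one base scene's responses across the levels of one parameter,
averaged over base scenes. In grouped mode, `class` variance is the
variance of class centers about their unweighted mean, and `non_class`
the mean within-class total variance.

**Invariance** is `1 − var_p / var_all` with `var_all` the total variance
of *all* conditions in the design about the global mean. The total (rather
than a per-parameter pool) makes invariance comparable across parameters.

**PCA-based factorization** projects the responses into the
*other-parameter subspace* and re-measures the parameter-induced variance
there. The subspace is built from exactly one vector per base scene — the
mean of that scene's responses over the parameter's levels — mean-centered
and decomposed by PCA, keeping the smallest leading set of components
whose cumulative explained variance reaches the threshold (default 0.9;
ties resolve to the smaller count; numerically zero components never
enter). Responses to other parameters' augmentations are *not* added as
separate points; the averaging-only reading keeps the subspace an
estimate of scene-driven (hence other-parameter-driven) structure.
Projections are affine: the subspace center is subtracted before
projecting. In grouped mode the other-structure for `class` is the pooled
within-class residuals and vice versa.

**Covariance-based factorization** is one minus the normalized Frobenius
inner product between the parameter's covariance (averaged over base
scenes) and the pooled covariance of all other parameters. It has no free
parameter and, for two parameters encoded along single axes at angle θ,
equals exactly `1 − cos²θ` (the Frobenius product of `uuᵀ` and `vvᵀ` is
`(u·v)²`).

Both scores lie in [0, 1] — the PCA variant because projection cannot
increase variance, the covariance variant by Cauchy–Schwarz — and all
scores are invariant to orthogonal transforms of the feature space.
Undefined scores (zero parameter variance, zero covariance, rank-0
subspaces) raise typed errors rather than returning sentinels, so they
can never silently enter a meta-analysis table.

**Within-subspace invariance** first builds the subspace of variance
*driven by* a target parameter (grouped mode: PCA of class centers —
the "identity subspace"; augmentation mode: PCA of the per-scene-centered
level deviations of the target parameter) and then measures invariance
inside it. At threshold 1.0 on full-rank data it reduces to plain
invariance.

**Dimensionality** is reported two ways: the component count reaching the
variance threshold (analogous to the PCA-based factorization), and the
participation ratio `(Σλ)² / Σλ²` of the covariance eigenvalues
(threshold-free, analogous to the covariance-based factorization).

**Movie variant.** For a time-ordered frame matrix, consecutive frame
pairs are treated as 2-level augmentations of a pseudo base scene (the
pair mean): within-pair differences are "local" (motion-driven) variance,
and the pair means stand in for all other sources. Both factorization
variants and invariance then follow the augmentation-mode definitions.
When the local variance is zero, factorization is undefined and the error
raised carries `invariance = 1.0` as an attribute.

## Rotation lesion and shuffle null

The lesion computes class centers `x^c`, the inter-class PCs (all
components of the centered centers with nonzero eigenvalue, M of them)
and the intra-class PCs (of the center-subtracted residuals), and applies
`x → g + W (x^c − g) + (x − x^c)` where `g` is the unweighted mean of
class centers and `W = Σ_{i≤M} v_i^intra (v_i^inter)ᵀ`. Design choices:

- **Centering.** The rotation is applied about `g` and `g` is added back.
  Rotating uncentered centers would shift the population grand mean
  arbitrarily; centering preserves it along with every conservation law
  (within-class deviations and covariance, inter-center spectrum,
  pairwise center distances — all asserted to 1e-8 in the tests).
- **Pairing depth.** M = rank of the inter-class covariance (≤ classes −
  1); the intra-class rank must reach M or the operation refuses (a
  typed rank error). Pairing beyond rank is undefined.
- **Sign convention.** Each PC's largest-magnitude coefficient is made
  positive, so `W` is reproducible across platforms.

The shuffle null permutes grouping labels (class labels in grouped mode;
base-scene assignments within each varied parameter in augmentation mode,
which keeps the level bookkeeping valid) and recomputes the metric. The
reported percentile is the strictly-less-than rank of the observed value
in the null, scaled to [0, 100] — deterministic under ties. Fewer than 20
permutations logs a warning (unstable percentile) but is not an error.

## Decoders

The binary few-shot simulation uses a linear-kernel SVM (the max-margin
decoder); multi-way identity decoding uses multinomial logistic
regression, whose class probabilities also feed the behavioral
signatures. Cross-validation is stratified (default 5 folds) with the
inverse-regularization strength chosen on a {0.01, 0.1, 1, 10, 100} grid
by an inner stratified loop on training folds only; a single-value grid
skips the inner loop. Solver tolerance is 1e-6 for reproducibility.

## Predictivity

**Encoding fits**: per outer fold, PCA is fit on the training conditions
only (top 300 components by default, or the training rank if smaller), a
ridge map is fit with its penalty selected by efficient leave-one-out
cross-validation within the training folds, and held-out conditions are
predicted. Each target's score is the Pearson correlation of its
concatenated held-out predictions with the truth; the aggregate is the
median over targets (robust to a few unpredictable units); constant
targets are recorded as missing and excluded. Fitting the PCA inside the
folds is deliberate — fitting it on all conditions would leak test
structure into the projection.

**RDM similarity** compares dot-product similarity matrices by Spearman
correlation over strictly-upper-triangle entries (average ranks on ties).
The stored object is a similarity matrix; the field often names the
corresponding construct a *dissimilarity* matrix, but only the rank
correlation matters and it is identical up to sign conventions applied to
both inputs.

**Behavioral signatures**: from classifier choice probabilities, the
image-by-distractor confusion rate is the two-alternative ratio
`I2_{i,d} = p_d / (p_true + p_d)` — the minimal probability-consistent
choice — and image difficulty `I1_i` is the mean of `1 − I2_{i,d}` over
defined distractors. Cells with `p_true + p_d = 0` are missing and are
pairwise-deleted in the Pearson comparisons. An alternative d′-based
transform exists in the behavioral-benchmarking literature; it is not
implemented here.

## Meta-analysis

Metrics and predictivity scores are averaged over each model's five final
layers (an explicit error if fewer are present), then correlated across
models by Spearman's rho, with uncertainty as the SD of rho over
bootstrap resamples of *models* (the exchangeable unit after layer
averaging). Combined-metric performance is an ordinary least-squares fit
of predictivity on the raw (unstandardized) metric columns over 80% of
models, scored by the Spearman correlation between predicted and actual
predictivity on the held-out 20%, averaged over 100 random splits.
Standardizing columns would change only the fitted weights, not the
held-out rank correlation.

## Synthetic data: what it emulates, and what it does not

All generators plant geometry via a single interpretable knob: the cosine
of the first principal angle between two subspaces, with all remaining
principal angles at 90°. Noise is isotropic Gaussian in feature space.
Identical configurations and seeds give bitwise-identical outputs.

- **Binary-feature code** (default 10 dimensions): each feature is a ±1
  coefficient on its own axis; the two decoder targets share an axis to a
  configurable degree. Training sets are balanced exactly (K per sign per
  target). Defaults for the quantities the few-shot sweep needs but the
  underlying design leaves open — test-set size 200, noise SD 0.5 — are
  package choices, exposed in the config. Note that even a noiseless
  orthogonal code does not decode perfectly at K = 2: a 4-point
  max-margin fit picks up nuisance features spuriously correlated with
  the label, which is precisely the few-shot fragility the simulation
  exists to demonstrate.
- **Augmentation-structured responses** (defaults: 100 base scenes × 10
  levels × 4 parameters = 4000 conditions, 50 units, unit latent
  variances): per-parameter orthonormal bases with configured pairwise
  alignments (exact when all parameters share one alignment value; the
  geometric mean of the pair otherwise), isotropic scene latents, and
  per-condition subspace offsets. Ground truth (bases, variances, sampled
  latents) is retained, so covariance-based factorization can be checked
  against the generating covariances. Because the scene latents are
  isotropic and fill the feature space, the *PCA-based* score is
  uniformly low on this generator regardless of the planted pairwise
  alignment — the 90% scene subspace overlaps every direction. The
  dedicated two-parameter oracle construction (`gen_two_param_oracle`,
  scene variance confined to the other parameter's axis) is the setting
  where both variants equal the closed form `1 − cos²θ` exactly, and is
  what the oracle tests and the acceptance script use.
- **Class-structured populations**: centers in a subspace at a planted
  angle to the within-class principal subspace, with a shared within-class
  spectrum. For the lesion to be well defined the spectrum must span at
  least `classes − 1` dimensions.
- **Movie trajectories**: pair means in a global subspace, within-pair
  differences in a local subspace at a planted angle.
- **Model zoo**: per-layer uniform metrics with a planted linear
  predictivity relationship plus noise, for validating the meta-analysis.

None of the generators emulate realistic tuning curves, firing-rate
nonnegativity, trial-to-trial noise correlations, or the heavy-tailed
eigenspectra of real cortical data; passing tests demonstrate that the
estimators recover planted geometry under clean conditions, not that real
data satisfy the generators' assumptions. Pixel-level image rendering is
out of scope: the augmentation design (which parameter varied, at which
level) is represented as metadata at the feature level.

## Numerical choices and problem sizes

- PCA everywhere is mean-centered SVD; components with eigenvalue below
  1e-12 of the leading one are treated as rank-deficient.
- Subspace orthonormality is validated to 1e-8; covariance symmetry to
  1e-10.
- The test suite and acceptance checks run at deliberately modest sizes —
  e.g. 8 classes × 20 conditions for the lesion, 200 shuffle-calibration
  replicates of a 6-class × 5-condition population with 99 permutations
  each, 100 sweep replicates per grid cell, 40 fabricated 200-model zoos —
  chosen so planted effects exceed sampling error by comfortable margins
  while the whole suite completes in minutes.

## Known limitations

- No noise-ceiling correction anywhere: predictivity scores are raw
  correlations, which rescales all models identically and does not affect
  model comparison, but absolute values are not comparable across
  datasets with different noise levels.
- Heterogeneous per-parameter alignments realize pairwise cosines only as
  the geometric mean of the two configured values.
- Grouped mode assumes classes are exchangeable and of comparable size;
  class centers are unweighted.
- The shuffle-null percentile is discrete (resolution 100/n_permutations).
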