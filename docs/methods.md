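# Methods

## Model and assumptions

asmbPLS-DA builds `J` orthogonal latent components for a multi-block
predictor `X = [X_1, ..., X_B]` and a dummy-coded categorical outcome `Y`.
Component extraction is NIPALS-style: the outcome summary `u` is initialised
to the first column of the centred `Y`; per block, the weight `X_b' u` is
normalised, soft-thresholded at the per-block sparsity quantile of its
absolute entries, renormalised to unit norm on its support, and turned into
a block score `t_b = X_b w_b / sqrt(m_b)` (block scaling prevents large
blocks from dominating purely by feature count); the super weight and super
score summarise the block scores, and `q` / `u = Y q` close the loop. The
iteration stops when the super score changes by less than `1e-8` in
relative norm (at most 500 iterations; with a single-column binary `Y` one
pass suffices). Both `X` and `Y` are deflated by the super-score regression
fit before the next component, which makes super scores of distinct
components exactly orthogonal.

The method assumes real-valued, complete data (no missing values — inputs
with missing cells are rejected at I/O), every group non-empty, and no
zero-variance feature (rejected, since scaling is undefined). It always
selects some features per block, so it is not designed for data with no
relevant features at all.

### Choices where the design was genuinely open

- **Quantile of absolute weights.** The soft-threshold level is the type-7
  empirical quantile of `|w|`, not of the signed weights: selection should
  be sign-symmetric, matching the `sign(x)(|x| - l)_+` form.
- **Quantile 0 is the dense limit.** At quantile exactly 0 the threshold is
  0 (no shrinkage), so a single dense block reproduces the classical PLS1
  weight `X'u / ||X'u||`. Any positive quantile uses the interpolated
  quantile of `|w|`, which shrinks the survivors by that amount before
  renormalisation.
- **Renormalisation after thresholding.** The unit-norm constraint is
  enforced on the sparse weight (post-thresholding), so the constraint
  holds exactly on the support. An all-zero weight after thresholding
  (possible only for constant `|w|`) is an error, not a silent skip.
- **Sign convention.** PLS weights are sign-ambiguous; each weight vector
  is flipped so its largest-magnitude entry is positive, with flips
  propagated so all stored quantities stay mutually consistent. This fixes
  reproducibility without changing predictions.
- **Prediction loadings.** `Y_predict` uses the regression loadings of the
  deflated `Y` on each super score (a least-squares reconstruction), while
  the unit-norm `q` directions are kept separately; for a binary outcome
  and one component the two formulations give identical classifications.

## Decision rules and votes

Fixed cutoff re-shifts the Y-estimate by the stored weighted-centring
offset and assigns group 1 above 0.5; exactly 0.5 goes to group 0, and all
argmin/argmax ties go to the lowest group index — deterministic and
documented. The distance rules operate on the model's super scores (all
fitted components) with centroids and the pooled within-group covariance
`S = sum_g (n_g - 1) S_g / (n - G)` estimated on the training scores;
Mahalanobis refuses singular or ill-conditioned `S` (condition number
>= 1e12) and suggests the Euclidean rule. PCA+MD fits a PCA on the training
Y-estimates (not the dummy `Y`), projects onto the first `G - 1`
components, and rejects rank-deficient estimates. Vote weights use
`log(BA / (1 - BA))` clamped to 0 for `BA <= 0.5` and capped at
`BA = 1 - 1e-6` to avoid infinite weights; ranked votes use average ranks
for ties. The per-rule CV metrics that feed the weighted and ranked votes
come from pooled out-of-fold predictions at the tuned quantile combination.

## Cross-validation tuning

Repeated stratified K-fold CV (defaults K = 5, N_CV = 10) tunes one
quantile combination per component, sequentially: candidates for component
`l` (the cartesian product of per-block candidate lists, in input order)
are scored by the flat mean of all K x N_CV fold balanced accuracies with
components `< l` frozen, and the highest-BA candidate wins, ties going to
the first candidate. The CV decision rule defaults to fixed cutoff
(binary) / Max Y (multiclass) and is configurable. The number of retained
components starts at 1 and grows while `BA_comp + 0.005 <= BA_{comp+1}`.
Candidates whose component fit fails (e.g. degenerate thresholding) score
BA 0. All fold assignments derive deterministically from one seed. Folds
are preprocessed once and deflated incrementally as components are frozen,
so a candidate evaluation costs a single component fit.

## Synthetic data generator

The generator emulates a two-block multi-omics design: a jointly
multivariate-normal "highly correlated" feature set (q_h in block 1, p_h in
block 2, pairwise correlations drawn Uniform(0.6, 0.9), which couples the
two blocks) and a remaining set with correlations Uniform(-0.5, 0.5).
Block-1 features have mean 0, variance 1; block-2 features mean 5,
variance 3. Raw correlation matrices of this kind are indefinite, so they
are repaired by flooring eigenvalues at `1e-8` of the largest and rescaling
the diagonal back to the target variances; this shrinks the realised
correlations somewhat (mean about 0.6 for the highly correlated set), which
is inherent to any eigenvalue-clipping repair. Defaults are n = 100,
q = 1000, q_h = 100, with (p, p_h) in {(50, 5), (200, 20), (1000, 100)}.

Only the first 10 features of block 1 and the first 5 of block 2 carry
non-zero outcome coefficients, drawn N(0, 5) per replicate (independent
draws across replicates, to average over effect configurations). The
`structure` setting permutes columns so the relevant positions are all
highly correlated (`cor`), exactly the first 6 + 3 (`order`), randomly
assigned (`random`), or none (`inverse`). Outcomes follow a logistic
(binary) or baseline-class softmax multinomial (three groups) model on the
centred-and-scaled blocks, plus a noise term `r * e`, `e ~ N(0, 5I)`, with
`r` in {0, 1, 2, 3, 5}; the multinomial class scores are exponentiated
after max-subtraction and normalised before the draw. Each replicate draws
train and test rows (n_test = n) as one MVN batch sharing the covariance,
structure map and coefficients; the batch is centred/scaled jointly before
the outcome model and then split, and the fitting pipeline receives the
original-scale matrices with its own preprocessing.

What the generator does **not** emulate: count-like marginals and
zero-inflation of sequencing data, batch effects, heavy tails, block-wise
missingness, and feature-count ratios beyond the configured blocks. Passing
tests on this generator show the algorithmic machinery recovers planted
linear-logistic signal under realistic correlation; they do not certify
performance on real sequencing data.

## Study sizes used in validation

The heavy validation runs (test suite and acceptance script) use a
scaled-down version of the full simulation study: the low-noise recovery
study runs 20 replicates of the (structure = cor, p = 50, p_h = 5, r = 0)
scenario at full data size (n = 100, q = 1000) with the p = 50 candidate
grids (block 1 {0.975, 0.98, 0.985, 0.99, 0.995}, block 2 {0.7, 0.9, 0.9})
and K = 5, N_CV = 10; feature selection is read off the full three-component
tuned fit, classification off the CV-selected component count. The
noise-monotonicity check uses reduced block sizes (q = 200) and fixed
quantiles, as only the qualitative trend is asserted. Under these
conditions the recovery study typically attains mean pooled selection
sensitivity around 0.55-0.6 with specificity above 0.95, and mean test
accuracy around 0.72-0.78 with the fixed-cutoff rule — for context, the
generating model's own Bayes accuracy averages about 0.9 here, because the
per-replicate random coefficients on strongly correlated features can
partially cancel, leaving some replicates intrinsically noisy.

## Numerical notes and limitations

- Tolerances: unit norms hold to 1e-10; super-score orthogonality and
  deflation residuals to 1e-8 (relative); NIPALS convergence 1e-8.
- Standard deviations use the n-1 (sample) convention throughout.
- Single-sample groups are allowed at fit; the Mahalanobis rule then
  refuses if the pooled covariance degenerates.
- Model JSON serialisation round-trips bit-exactly (shortest-repr floats).
- Internally indices are 0-based; human-readable reports use feature names.
- No missing-value handling, no continuous-outcome regression mode, no
  out-of-core or GPU path. Lasso-type competitors, LDA and random forest
  are reached through scikit-learn adapters only.
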