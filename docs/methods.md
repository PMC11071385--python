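# Methods

## Model and assumptions

Measurements are an array `X` of shape `(n units, c conditions, t trials)`
with `c >= 2` and `t >= 2`.  The generative model is additive and
independent: the response on a trial of condition `j` is
`x = s_j + e`, where `s_j` is a condition-specific draw from a signal
distribution with mean `mu_signal` and covariance `Sigma_signal`, shared
by all `t` trials of that condition, and `e` is a fresh zero-mean noise
draw with covariance `Sigma_noise`, independent of the signal and across
trials.  Only first and second moments are estimated; Gaussianity is
assumed only where likelihoods are evaluated (shrinkage cross-validation)
and where synthetic data are sampled.  The model implies, for
trial-averaged data, `Sigma_data[t] = Sigma_signal + Sigma_noise / t`:
trial averaging attenuates noise but never removes it, which is why the
sample covariance of trial-averaged responses ("naive" signal estimate)
is biased upward and the aggregated-residual noise estimate (denominator
`ct - 1` instead of the correct pooled `c(t-1)`) is biased downward by
the factor `c(t-1)/(ct-1)`.

Missing values are rejected on load: every estimator assumes complete
`t`-trial blocks.

## Estimation algorithm

1. Pool the Bessel-corrected trial covariance over conditions and shrink:
   `Sigma_noise_orig = s(mean_j cov(X_j))`.
2. Fix the noise mean at zero.
3. Estimate the trial-averaged data moments, with shrinkage on the
   covariance: `mu_data = mean(Xbar)`, `Sigma_data = s(cov(Xbar))`.
4. Subtract: `Sigma_signal = Sigma_data - Sigma_noise / t`,
   `mu_signal = mu_data`.
5. If `Sigma_signal` is PSD (minimum eigenvalue above
   `-1e-10 * max(largest eigenvalue, 1)`), stop with zero iterations.
6. Otherwise alternate until convergence:
   - `Sigma_signal <- PSD(Sigma_data - Sigma_noise / t)`;
   - `Sigma_noise <- PSD(w1 * Sigma_noise_orig + w2 * t * (Sigma_data -
     Sigma_signal))` with `w1 = c t^2 (t-1) / (c t^2 (t-1) + c - 1)` and
     `w2 = 1 - w1`, weights that reflect the effective sample sizes behind
     the two available noise estimators;
   - stop when the element-wise Pearson correlations between successive
     signal estimates and successive noise estimates both exceed the
     convergence threshold (default 0.999).

The refinement is biconvex and converges in a handful of passes in
practice (never more than 2 across the simulation grids exercised by the
test suite and acceptance script).  A hard cap (default 50) turns
pathological numerics into an error rather than a silent bad estimate.
The estimates are consistent: the initial subtraction estimator is
unbiased, and for growing data the probability that it leaves the PSD
cone vanishes, so the constrained estimates inherit its asymptotics.
Because the PSD cone is convex, projecting onto it can only reduce the
Frobenius distance to the true (PSD) covariances.

Design choices where the procedure was open:

* The convergence correlation is computed over all `n^2` matrix elements
  (symmetric-safe; an upper-triangle variant differs immaterially).
* The first refinement pass compares against the Step-4/Step-1 initial
  estimates.
* Shrinkage fractions are selected once, in Steps 1 and 3, and held fixed
  inside the loop: the loop only re-mixes already-estimated matrices, so
  there is nothing new to cross-validate.
* The cross-validation seed is the only source of randomness; with
  shrinkage disabled the estimator is fully deterministic.

## Shrinkage

`s(Sigma) = lambda * Sigma + (1 - lambda) * Sigma_diag` with
`lambda in [0, 1]`; the target keeps the sample variances on the diagonal
so only covariances are biased toward zero.  `lambda` is selected by a
single random 80/20 train/test split (default `leaveout = 0.2`),
scanning candidates 0 to 1 in steps of 0.02 (51 values) and minimizing
the mean held-out Gaussian negative log likelihood; candidates that are
not positive definite score infinity and are never selected (this alone
forces genuine shrinkage whenever the training sample covariance is
singular).  Exact NLL ties break toward the larger fraction (less bias).
With `want_full` (default on), the selected fraction is re-applied to the
covariance of the full dataset — slightly more shrinkage than optimal in
exchange for using all the data.

Split axes and corner cases:

* **Data mode** (Step 3): the samples are the `c` trial-averaged rows;
  conditions are split.  Held-out rows are scored against the
  training-set mean (a test-derived mean would leak held-out data).
* **Noise mode** (Step 1), `t >= 3`: trial indices are split globally
  (training `ceil(0.8 t)`, clipped to `[2, t-1]`).  The training pooled
  covariance is scored on held-out trials after removing each condition's
  mean.  When two or more test trials per condition exist, that mean is
  the test-set condition mean.  When exactly one test trial per condition
  remains (any `t` from 3 to 6 at the default leaveout), the test-set
  mean would be the test trial itself, zeroing every residual and
  reducing the NLL to a log-determinant race; in that case the
  training-set condition mean is subtracted instead — it removes the
  condition's signal draw exactly (the draw is shared across trials) and
  leaks nothing.
* **Noise mode, `t = 2`**: no trial split can leave two training trials
  per condition, so the split falls back to holding out whole conditions:
  the pooled covariance of 80% of conditions is scored on the remaining
  conditions' own-mean residuals.  An explicit `noise_fraction` bypasses
  cross-validation entirely.

The split is a single random partition, not repeated K-fold, with an
exposed seed; averaging over repeated splits is a possible extension but
changes none of the package's guarantees.

## PSD projection

The Frobenius-nearest symmetric PSD matrix: symmetrize, take the SVD, and
average the matrix with its symmetric polar factor; equivalent to
clipping negative eigenvalues to zero (the equivalence is an explicit
test oracle).  If round-off leaves the result indefinite, `1e-10 * I` is
added and the procedure restarts, at most 100 times.

## Baseline estimators

* **Naive**: signal = sample covariance of trial averages; noise =
  aggregated within-condition residual covariance with denominator
  `ct - 1`.
* **Split-half**: trials are split into halves (`ceil(t/2)` /
  `floor(t/2)`), trial-averaged, column-centered, and the symmetrized
  cross-covariance `(Y1' Y2 + Y2' Y1) / (2(c-1))` averaged over 10 random
  splits (default).  Noise is independent across halves, so the estimate
  is unbiased for the signal covariance.
* **cvPCA**: per split, both halves are projected onto the principal
  components of the first half's trial-averaged covariance; the
  per-dimension dot product of the projections, divided by `c - 1` so the
  output lives on the covariance-eigenvalue scale, estimates the signal
  eigenspectrum.  `min(n, c-1)` dimensions are retained; negative values
  are averaged as-is, not floored.
* **MEME**: normalized signal eigenmoments `m_k = tr(Sigma_signal^k)/n`
  are estimated without bias by partitioning the conditions into `k`
  disjoint groups, forming each group's centered cross-half covariance
  `C_g = Y1' Y2 / (c_g - 1)` (unbiased, noise-independent across halves)
  and taking `tr(C_1 ... C_k)/n` — the groups are independent, so the
  expectation factorizes.  This construction trades some variance for
  exact unbiasedness, which is verified by a 2,000-simulation
  Monte-Carlo gate in the test suite.  A power-law spectrum
  `lambda_d = A d^(-alpha)` is then fit to the five (default) moments by
  bounded least squares over `(log A, alpha)` with relative-error
  residuals (weights `max(|m_k|, 1e-3 max|m|)`), so every moment order
  carries comparable influence; default initialization is `alpha = 1`,
  `A` = first eigenmoment, and the simulation harness may pass
  ground-truth initial values.  Optimizer failure is flagged in the
  result, never silently dropped.

## Eigenspectrum analytics

Effective dimensionality `ED = (sum lambda)^2 / sum lambda^2` is
scale-invariant and ranges from 1 to `n` for nonnegative spectra; it is
computed on spectra as given (naive or split-half spectra may contain
negative eigenvalues).  The power-law slope is fit by least squares in
log-log space at indices drawn from a log-spaced grid (granularity at
least as fine as `log(d) - log(d-1)`, rounded to integers and
deduplicated — duplicate indices would double-weight points), keeping
only eigenvalues above 0.001 of the maximum (threshold relaxed tenfold
until at least two qualify); negative and zero eigenvalues can therefore
never enter the fit.  The exponent is reported as the negated slope.
Sign conventions for principal components: flip a component if its mean
is negative; in paired (split-half) analyses additionally flip the
partner's columns so cross-half cosines are non-negative; in
multi-subject score comparisons, iteratively flip any subject whose
scores correlate negatively with the average of the others.  Eigenvalue
ties leave the eigenvector order to the decomposition routine;
reliability analyses must tolerate this.

## Synthetic data and benchmark

The simulator draws, per condition, one signal sample and `t` independent
noise samples from multivariate Gaussians and adds them — exactly the
generative model above.  Two scenario families ship with the package: a
10-unit block-correlated scenario (signal: unit variances, covariance 0.5
among units 1–5; noise: variances 2, covariance 1 among units 4–8; both
zero-mean; closed-form eigenspectra {3, 1x5, 0.5x4} and {6, 2x5, 1x4},
both with ED = 6.67), and zero-mean power-law scenarios (`n` = 10 or 50;
spectrum `d^(-alpha)`; random orthonormal eigenvectors held fixed across
exponents for a given `(n, seed)` and independent between signal and
noise).  A third, user-supplied family (arbitrary ground-truth covariance
pairs read from HDF5 containers) supports empirically derived ground
truths.  Gaussian sampling goes through an eigendecomposition with
clipped negatives, so rank-deficient covariances are handled by fixing
zero-variance directions at zero.

The benchmark derives every dataset from a `SeedSequence` keyed by
`(master seed, scenario, c, t, simulation)` and every method's internal
randomness from the same key extended with a fixed per-method integer —
so results are bit-reproducible and adding a method never perturbs data
generation.  Recovery is scored by R² over the upper triangle (including
the diagonal) of the covariance against ground truth, and by the ED and
power-law exponent of the estimated spectra against the ground-truth
values.

Problem sizes in the shipped tests were chosen to make Monte-Carlo checks
decisive at three standard errors while keeping the suite quick: 2,000
simulations for unbiasedness identities at `c = 50, t = 5`; 100–200
simulations per cell for recovery trends over `c` up to 1,600; 20 per
cell for dimensionality tracking up to `c = 10,000`.  Monte-Carlo
tolerances are three standard errors of the mean, computed from the
simulations themselves (a slightly wider 3.2 SE is used for element-wise
checks across all `n(n+1)/2` covariance entries, where the multiplicity
of comparisons makes a 3.0 SE excursion in some entry likely by chance).

### What the simulations do and do not show

The generator emulates Gaussian, condition-independent, additive noise
with a stationary covariance.  Real neural data can violate each of these
assumptions: heavy-tailed responses, stimulus-dependent noise,
nonstationarity across sessions (the per-session z-scoring helper exists
for this reason), and temporal dependence between trials.  Passing tests
demonstrate correctness of the estimators under the model, plus
finite-sample behavior (shrinkage benefits, PSD-constraint effects,
estimator biases) — they do not certify that the model describes any
particular dataset.  The fit-then-synthesize path exists precisely to
check a fitted model against the raw data distribution.

## Known limitations

* Point estimates only; no posterior or bootstrap uncertainty.
* The noise model is condition-independent and additive; Poisson-like or
  signal-dependent variability is out of scope.
* Shrinkage cross-validation at `t = 2` rests on the condition-split
  fallback described above, which scores within-condition residual pairs
  that are perfectly anticorrelated; its selected fractions are sensible
  in practice but the held-out score is not a proper likelihood there.
* The MEME eigenmoment estimator's variance grows quickly with the moment
  order at small `c` (each of the `k` condition groups must still be
  sizeable); with fewer than `2k` conditions the estimator refuses to
  run.
* Broken power-law spectra are not fit; the parametric family is a single
  unbroken power law.
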