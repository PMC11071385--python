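# gsnkit

Generative modeling of signal and noise (GSN) for repeated-trial
multivariate measurements.

## The problem

Suppose you record `n` units (voxels, vertices, neurons, channels) to `c`
conditions (e.g. stimuli), repeating each condition for `t` trials.  The
response on each trial is modeled as the sum of two independent draws:

* a **signal** draw, shared by all trials of a condition, with mean
  `mu_signal` and covariance `Sigma_signal`, and
* a zero-mean **noise** draw, fresh on every trial, with covariance
  `Sigma_noise`.

Because signal and noise are independent and additive,

```
mu_data[t]    = mu_signal
Sigma_data[t] = Sigma_signal + Sigma_noise / t
```

for trial-averaged data.  Averaging over trials attenuates noise by `1/t`
but never removes it — the sample covariance of trial-averaged responses
(the "naive" signal estimate) is biased upward by `Sigma_noise / t`, and
downstream analyses such as PCA inherit that bias.  GSN estimates
`Sigma_noise` from the trial-to-trial covariance pooled over conditions,
estimates `Sigma_data[t]` from the trial-averaged responses, and recovers
the signal covariance by subtraction, with two safeguards:

* **Shrinkage regularization**: both covariance estimates can be shrunk
  toward their diagonals, `s(Sigma) = lambda*Sigma + (1-lambda)*Sigma_diag`,
  with the fraction `lambda` chosen by cross-validated held-out Gaussian
  likelihood.
* **Positive semi-definite constraint**: if the subtraction leaves the PSD
  cone, an alternating biconvex refinement projects the signal estimate
  onto the cone (Frobenius-nearest PSD matrix) and re-mixes the noise
  estimate as a sample-size-weighted average of its two available
  estimators, until successive estimates correlate above 0.999.

The package also provides baseline estimators for comparison (naive,
split-half covariance, cross-validated PCA, and MEME power-law eigenmoment
matching), eigenspectrum analytics (effective dimensionality
`ED = (sum lambda)^2 / sum lambda^2`, log-log power-law slope fitting,
sign-aligned PC reliability), a ground-truth simulation benchmark, and
sampling of synthetic data from a fitted model.

## Worked example

```python
import gsnkit as g

scen  = g.make_simple_scenario()                 # known 10-unit ground truth
data  = g.synthesize(scen, c=200, t=4, seed=0)   # (units, conditions, trials)
model = g.GSN(random_state=0).fit(data)          # shrinkage on by default

print(model.shrinkage_noise_, model.shrinkage_data_)   # 0.72 0.82
print(model.n_iter_, model.converged_)                 # 0 True
print(g.recovery_r2(model.signal_cov_, scen.signal.covariance))  # 0.909
print(g.recovery_r2(model.noise_cov_,  scen.noise.covariance))   # 0.965
```

The fitted estimator exposes `signal_mean_`, `signal_cov_`, `noise_cov_`,
`data_cov_`, the selected shrinkage fractions, and the refinement
iteration count (`n_iter_` is 0 here because the subtraction was already
PSD).  The recovery scores are the coefficient of determination over the
upper triangle of each covariance matrix against the known ground truth:
GSN recovers the off-diagonal signal structure (e.g. entry (1,2) is
estimated at 0.487 against a true 0.5), while the naive trial-averaged
estimate for the same entry is 0.617 — inflated by residual noise
covariance.  Eigenspectrum summaries behave accordingly: the true signal
effective dimensionality is 100/15 = 6.67, the GSN estimate is 7.02.

The same functionality is scriptable from the shell:

```sh
gsnkit simulate --scenario simple --c-grid 50,200 --t-grid 4 \
    --methods gsn,gsn-noshrink,naive --nsims 50 --seed 1 --out bench.csv
gsnkit fit responses.h5 --seed 1 --output fit.h5
gsnkit metrics --cov signal_cov.csv
gsnkit synthesize --fit fit.h5 --c 100 --t 3 --seed 2 --out synth.h5
```

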