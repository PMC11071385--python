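"""The GSN estimator: decompose repeated-trial measurements into signal
and noise distributions.

Model
-----
Each trial's response (1 x n) is the sum of a condition-specific draw from
a signal distribution (mean ``mu_signal``, covariance ``Sigma_signal``) and
an independent zero-mean noise draw (covariance ``Sigma_noise``).  Signal
and noise add, so trial-averaged data over ``t`` trials satisfy the moment
identities

    mu_data[t]    = mu_signal
    Sigma_data[t] = Sigma_signal + Sigma_noise / t.

Fitting estimates ``Sigma_noise`` from pooled within-condition trial
covariance, ``Sigma_data[t]`` from the trial-averaged responses (both
optionally shrunk toward their diagonals), and obtains the signal
covariance by subtraction.  When the subtraction leaves the positive
semi-definite cone, an alternating biconvex refinement projects the signal
estimate onto the PSD cone and re-mixes the noise estimate as a
sample-size-weighted average of its two available estimators, iterating
until successive estimates stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data import (
    GaussianMoments,
    as_response_data,
    pooled_noise_covariance,
    sample_covariance,
    trial_average,
)
from .psd import is_psd, nearest_psd
from .shrinkage import apply_shrinkage, cv_select_shrinkage

__all__ = [
    "GSNResult",
    "GSN",
    "perform_gsn",
    "noise_update",
    "noise_update_weights",
    "convergence_check",
]


@dataclass
class GSNResult:
    """Full output of a GSN fit."""

    signal: GaussianMoments
    noise: GaussianMoments
    data_trialavg: GaussianMoments
    noise_orig_cov: np.ndarray
    shrinkage_noise: float
    shrinkage_data: float
    iterations: int
    converged: bool
    n_conditions: int = 0
    n_trials: int = 0


def noise_update_weights(c: int, t: int) -> tuple[float, float]:
    """Weights of the two noise-covariance estimators in the refinement.

    The pooled within-condition estimate rests on ``c*t^2*(t-1)`` effective
    observations and the data-minus-signal subtraction on ``c-1``; the
    update takes their convex combination
    ``w1 = c t^2 (t-1) / (c t^2 (t-1) + c - 1)``, ``w2 = 1 - w1``.
    """
    if c < 2 or t < 2:
        raise ValueError("weights require c >= 2 and t >= 2")
    denom = c * t**2 * (t - 1) + c - 1
    return c * t**2 * (t - 1) / denom, (c - 1) / denom


def noise_update(
    noise_orig_cov: np.ndarray,
    data_cov: np.ndarray,
    signal_cov: np.ndarray,
    c: int,
    t: int,
) -> np.ndarray:
    """Weighted average of the two noise-covariance estimates, projected
    onto the PSD cone."""
    noise_orig_cov = np.asarray(noise_orig_cov, dtype=float)
    data_cov = np.asarray(data_cov, dtype=float)
    signal_cov = np.asarray(signal_cov, dtype=float)
    if not (noise_orig_cov.shape == data_cov.shape == signal_cov.shape):
        raise ValueError("covariance shapes do not match")
    w1, w2 = noise_update_weights(c, t)
    mixed = w1 * noise_orig_cov + w2 * t * (data_cov - signal_cov)
    return nearest_psd(mixed)


def convergence_check(previous: np.ndarray, current: np.ndarray, threshold: float) -> bool:
    """True when the element-wise Pearson correlation of two successive
    covariance estimates exceeds ``threshold``.

    A constant matrix has no correlation defined; it is treated as
    converged only when the two matrices are element-wise equal (1e-12).
    """
    previous = np.asarray(previous, dtype=float).ravel()
    current = np.asarray(current, dtype=float).ravel()
    if previous.shape != current.shape:
        raise ValueError("matrices must have the same shape")
    dp = previous - previous.mean()
    dc = current - current.mean()
    np_, nc = np.linalg.norm(dp), np.linalg.norm(dc)
    if np_ == 0.0 or nc == 0.0:
        return bool(np.max(np.abs(previous - current)) <= 1e-12)
    return bool(float(dp @ dc) / (np_ * nc) > threshold)


class GSN(BaseEstimator):
    """Estimate signal and noise distributions from repeated-trial data.

    Parameters
    ----------
    want_shrinkage : bool, default True
        Shrink the noise and data covariance estimates toward their
        diagonals with cross-validated intensity.  When False the
        shrinkage operator is the identity (fraction 1).
    noise_fraction, data_fraction : float, optional
        Explicit shrinkage fractions; bypass cross-validation for the
        corresponding covariance.
    shrinkage_fractions : array-like, optional
        Candidate grid for cross-validation (default 0 to 1 by 0.02).
    leaveout : float, default 0.2
        Held-out fraction in the shrinkage cross-validation split.
    want_full : bool, default True
        Re-apply the selected fraction to the full-data covariance.
    convergence_threshold : float, default 0.999
        Element-wise correlation between successive estimates above which
        the refinement loop stops.
    max_iterations : int, default 50
        Hard cap on refinement passes; exceeding it raises.
    random_state : int, Generator, or None
        Governs only the shrinkage cross-validation splits; the estimator
        itself is deterministic.

    Attributes
    ----------
    signal_mean_, signal_cov_, noise_mean_, noise_cov_ : fitted moments
    data_mean_, data_cov_ : moments of the trial-averaged data
    noise_orig_cov_ : initial (pooled, shrunk) noise covariance
    shrinkage_noise_, shrinkage_data_ : fractions actually applied
    n_iter_ : refinement passes used (0 when the subtraction is already PSD)
    converged_ : bool
    result_ : GSNResult
    """

    def __init__(
        self,
        want_shrinkage: bool = True,
        noise_fraction=None,
        data_fraction=None,
        shrinkage_fractions=None,
        leaveout: float = 0.2,
        want_full: bool = True,
        convergence_threshold: float = 0.999,
        max_iterations: int = 50,
        random_state=None,
    ):
        self.want_shrinkage = want_shrinkage
        self.noise_fraction = noise_fraction
        self.data_fraction = data_fraction
        self.shrinkage_fractions = shrinkage_fractions
        self.leaveout = leaveout
        self.want_full = want_full
        self.convergence_threshold = convergence_threshold
        self.max_iterations = max_iterations
        self.random_state = random_state

    def fit(self, X, y=None):
        rd = as_response_data(X)
        n, c, t = rd.shape
        rng = np.random.default_rng(self.random_state)

        # Step 1: pooled within-condition noise covariance, shrunk
        noise_orig, frac_noise = self._shrunk(rd, "noise", rng)
        noise_cov = noise_orig

        # Step 2: the noise is zero-mean by assumption
        noise_mean = np.zeros(n)

        # Step 3: moments of the trial-averaged data, shrunk
        xbar = trial_average(rd)
        data_mean = xbar.mean(axis=0)
        data_cov, frac_data = self._shrunk(xbar, "data", rng)

        # Step 4: signal by subtraction
        signal_cov = data_cov - noise_cov / t
        signal_mean = data_mean - noise_mean

        # Step 5: done if already PSD, else alternate (Step 6)
        iterations = 0
        converged = True
        if not is_psd(signal_cov):
            prev_signal, prev_noise = signal_cov, noise_cov
            converged = False
            while iterations < self.max_iterations:
                iterations += 1
                signal_cov = nearest_psd(data_cov - noise_cov / t)
                noise_cov = noise_update(noise_orig, data_cov, signal_cov, c, t)
                if convergence_check(
                    prev_signal, signal_cov, self.convergence_threshold
                ) and convergence_check(
                    prev_noise, noise_cov, self.convergence_threshold
                ):
                    converged = True
                    break
                prev_signal, prev_noise = signal_cov, noise_cov
            if not converged:
                raise RuntimeError(
                    f"GSN refinement did not converge within "
                    f"{self.max_iterations} iterations"
                )

        self.signal_mean_ = signal_mean
        self.signal_cov_ = signal_cov
        self.noise_mean_ = noise_mean
        self.noise_cov_ = noise_cov
        self.data_mean_ = data_mean
        self.data_cov_ = data_cov
        self.noise_orig_cov_ = noise_orig
        self.shrinkage_noise_ = frac_noise
        self.shrinkage_data_ = frac_data
        self.n_iter_ = iterations
        self.converged_ = converged
        self.result_ = GSNResult(
            signal=GaussianMoments(signal_mean, 0.5 * (signal_cov + signal_cov.T)),
            noise=GaussianMoments(noise_mean, 0.5 * (noise_cov + noise_cov.T)),
            data_trialavg=GaussianMoments(data_mean, data_cov),
            noise_orig_cov=noise_orig,
            shrinkage_noise=frac_noise,
            shrinkage_data=frac_data,
            iterations=iterations,
            converged=converged,
            n_conditions=c,
            n_trials=t,
        )
        return self

    def _shrunk(self, data, mode: str, rng) -> tuple[np.ndarray, float]:
        """Covariance for one mode with whatever shrinkage policy applies."""
        explicit = self.noise_fraction if mode == "noise" else self.data_fraction
        if mode == "noise":
            raw = pooled_noise_covariance(data)
        else:
            raw = sample_covariance(np.asarray(data))
        if not self.want_shrinkage:
            return raw, 1.0
        if explicit is not None:
            return apply_shrinkage(raw, float(explicit)), float(explicit)
        res = cv_select_shrinkage(
            data,
            mode=mode,
            leaveout_fraction=self.leaveout,
            candidate_fractions=self.shrinkage_fractions,
            want_full=self.want_full,
            random_state=rng,
        )
        return res.covariance, res.selected_fraction


def perform_gsn(data, **kwargs) -> GSNResult:
    """Functional wrapper around :class:`GSN`; returns the
    :class:`GSNResult`."""
    return GSN(**kwargs).fit(data).result_
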