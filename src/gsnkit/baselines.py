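"""Comparison estimators of the signal covariance / eigenspectrum.

Three estimators from the literature serve as baselines for GSN:

* **Split-half** — symmetrized cross-covariance of trial-averaged halves
  of the trials; the noise is independent across halves, so it cancels in
  expectation and the estimate is unbiased for the signal covariance.
* **cvPCA** — project both halves onto the principal components of the
  first half and take per-dimension dot products of the projections; an
  estimate of the signal eigenspectrum.
* **MEME** (minimize eigenmoment error) — estimate the first few moments
  of the signal eigenvalue distribution unbiasedly from cross-half
  statistics, then fit a parametric power-law spectrum
  ``lambda_d = A * d**(-alpha)`` whose moments match.

All three average over repeated random splits of the trials (10 by
default; nearly equal halves when t is odd).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .data import as_response_data

__all__ = [
    "SplitConfig",
    "split_half_signal_cov",
    "cvpca_signal_eigenspectrum",
    "estimate_signal_eigenmoments",
    "meme_signal_eigenspectrum",
    "SplitHalfCovariance",
    "CVPCA",
    "MEMESpectrum",
]


@dataclass
class SplitConfig:
    """Number of random trial splits and the seed that drives them."""

    n_splits: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def _split_halves(values: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Centered trial-averaged (c, n) matrices for one random split of the
    trials into halves of sizes ceil(t/2) and floor(t/2)."""
    n, c, t = values.shape
    perm = rng.permutation(t)
    h1, h2 = perm[: (t + 1) // 2], perm[(t + 1) // 2 :]
    y1 = values[:, :, h1].mean(axis=2).T
    y2 = values[:, :, h2].mean(axis=2).T
    return y1 - y1.mean(axis=0), y2 - y2.mean(axis=0)


def split_half_signal_cov(data, n_splits: int = 10, random_state=None) -> np.ndarray:
    """Signal covariance as the symmetrized cross-covariance of two trial
    halves, ``(Ydot1^T Ydot2 + Ydot2^T Ydot1) / (2 (c - 1))``, averaged
    over random splits."""
    rd = as_response_data(data)
    n, c, t = rd.shape
    rng = np.random.default_rng(random_state)
    acc = np.zeros((n, n))
    for _ in range(n_splits):
        y1, y2 = _split_halves(rd.values, rng)
        cross = y1.T @ y2 / (c - 1)
        acc += 0.5 * (cross + cross.T)
    return acc / n_splits


def cvpca_signal_eigenspectrum(data, n_splits: int = 10, random_state=None) -> np.ndarray:
    """Cross-validated PCA estimate of the signal eigenspectrum.

    Per split, principal components of the first half's trial-averaged
    covariance are computed; both halves are projected onto them and the
    per-dimension dot product of the projections, scaled by 1/(c-1), is
    the eigenvalue estimate.  The output keeps the min(n, c-1) dimensions
    supported by the data rank and is averaged over splits (no flooring of
    negative values).
    """
    from .eigen import eigendecompose

    rd = as_response_data(data)
    n, c, t = rd.shape
    rng = np.random.default_rng(random_state)
    k = min(n, c - 1)
    acc = np.zeros(k)
    for _ in range(n_splits):
        y1, y2 = _split_halves(rd.values, rng)
        V = eigendecompose(y1.T @ y1 / (c - 1)).eigenvectors[:, :k]
        acc += np.einsum("ci,ci->i", y1 @ V, y2 @ V) / (c - 1)
    return acc / n_splits


def estimate_signal_eigenmoments(
    data, n_moments: int = 5, n_splits: int = 10, random_state=None
) -> np.ndarray:
    """Unbiased estimates of the first ``n_moments`` normalized signal
    eigenmoments ``m_k = (1/n) tr(Sigma_signal^k)``.

    For moment k, the conditions are partitioned into k disjoint groups;
    each group's centered cross-half covariance ``C_g = Ydot1^T Ydot2 /
    (c_g - 1)`` is an independent unbiased estimate of the signal
    covariance (the noise is independent across trial halves), so the
    product trace ``tr(C_1 ... C_k)`` is exactly unbiased for
    ``tr(Sigma_signal^k)``.  Estimates are averaged over random trial
    splits (and random condition partitions).
    """
    rd = as_response_data(data)
    n, c, t = rd.shape
    if c < 2 * n_moments:
        raise ValueError(
            f"need at least {2 * n_moments} conditions for {n_moments} moments"
        )
    rng = np.random.default_rng(random_state)
    acc = np.zeros(n_moments)
    for _ in range(n_splits):
        perm = rng.permutation(t)
        h1, h2 = perm[: (t + 1) // 2], perm[(t + 1) // 2 :]
        y1 = rd.values[:, :, h1].mean(axis=2).T
        y2 = rd.values[:, :, h2].mean(axis=2).T
        cperm = rng.permutation(c)
        for k in range(1, n_moments + 1):
            prod = None
            for grp in np.array_split(cperm, k):
                a = y1[grp] - y1[grp].mean(axis=0)
                b = y2[grp] - y2[grp].mean(axis=0)
                C = a.T @ b / (grp.size - 1)
                prod = C if prod is None else prod @ C
            acc[k - 1] += np.trace(prod) / n
    return acc / n_splits


def _powerlaw_moments(log_a: float, alpha: float, n: int, n_moments: int) -> np.ndarray:
    d = np.arange(1, n + 1, dtype=float)
    k = np.arange(1, n_moments + 1, dtype=float)
    return np.exp(k * log_a) * np.mean(
        d[None, :] ** (-alpha * k[:, None]), axis=1
    )


def meme_signal_eigenspectrum(
    data,
    n_moments: int = 5,
    init_exponent: float = 1.0,
    init_intercept: float | None = None,
    n_splits: int = 10,
    random_state=None,
):
    """Signal eigenspectrum via moment matching to a power law.

    Estimated eigenmoments are matched, in weighted least squares over
    ``(log A, alpha)``, by the moments of the model spectrum
    ``lambda_d = A * d**(-alpha)``, ``d = 1..n``.  Residuals are relative
    errors (weights ``max(|m_k|, 1e-3 * max|m|)``) so all moment orders
    carry comparable influence.  One fit per trial split; spectrum and
    parameters are averaged across splits.

    Returns ``(eigenvalues, exponent, intercept, converged)``; a failed
    optimization is flagged through ``converged`` rather than silently
    dropped.
    """
    rd = as_response_data(data)
    n = rd.n_units
    rng = np.random.default_rng(random_state)
    d = np.arange(1, n + 1, dtype=float)

    spectra, exponents, intercepts = [], [], []
    converged = True
    for _ in range(n_splits):
        m_hat = estimate_signal_eigenmoments(
            rd, n_moments=n_moments, n_splits=1, random_state=rng
        )
        weights = np.maximum(np.abs(m_hat), 1e-3 * np.max(np.abs(m_hat)))
        weights = np.maximum(weights, 1e-300)
        a0 = (
            float(init_intercept)
            if init_intercept is not None
            else max(float(m_hat[0]), 1e-12)
        )

        def residuals(p):
            return (_powerlaw_moments(p[0], p[1], n, n_moments) - m_hat) / weights

        sol = least_squares(
            residuals,
            x0=[np.log(a0), float(init_exponent)],
            bounds=([-50.0, 0.0], [50.0, 20.0]),
            method="trf",
        )
        converged = converged and bool(sol.success)
        log_a, alpha = sol.x
        spectra.append(np.exp(log_a) * d ** (-alpha))
        exponents.append(float(alpha))
        intercepts.append(float(np.exp(log_a)))

    return (
        np.mean(spectra, axis=0),
        float(np.mean(exponents)),
        float(np.mean(intercepts)),
        converged,
    )


class SplitHalfCovariance(BaseEstimator):
    """Split-half signal covariance estimator.

    Attributes (after fit): ``covariance_``.
    """

    def __init__(self, n_splits: int = 10, random_state=None):
        self.n_splits = n_splits
        self.random_state = random_state

    def fit(self, X, y=None):
        self.covariance_ = split_half_signal_cov(
            X, n_splits=self.n_splits, random_state=self.random_state
        )
        return self


class CVPCA(BaseEstimator):
    """Cross-validated PCA signal eigenspectrum estimator.

    Attributes (after fit): ``eigenvalues_``.
    """

    def __init__(self, n_splits: int = 10, random_state=None):
        self.n_splits = n_splits
        self.random_state = random_state

    def fit(self, X, y=None):
        self.eigenvalues_ = cvpca_signal_eigenspectrum(
            X, n_splits=self.n_splits, random_state=self.random_state
        )
        return self


class MEMESpectrum(BaseEstimator):
    """Power-law signal eigenspectrum by eigenmoment matching (MEME).

    Attributes (after fit): ``eigenvalues_``, ``exponent_``,
    ``intercept_``, ``eigenmoments_``, ``converged_``.
    """

    def __init__(
        self,
        n_moments: int = 5,
        init_exponent: float = 1.0,
        init_intercept=None,
        n_splits: int = 10,
        random_state=None,
    ):
        self.n_moments = n_moments
        self.init_exponent = init_exponent
        self.init_intercept = init_intercept
        self.n_splits = n_splits
        self.random_state = random_state

    def fit(self, X, y=None):
        rng = np.random.default_rng(self.random_state)
        self.eigenmoments_ = estimate_signal_eigenmoments(
            X, n_moments=self.n_moments, n_splits=self.n_splits, random_state=rng
        )
        spec, expo, icept, ok = meme_signal_eigenspectrum(
            X,
            n_moments=self.n_moments,
            init_exponent=self.init_exponent,
            init_intercept=self.init_intercept,
            n_splits=self.n_splits,
            random_state=rng,
        )
        self.eigenvalues_ = spec
        self.exponent_ = expo
        self.intercept_ = icept
        self.converged_ = ok
        return self
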