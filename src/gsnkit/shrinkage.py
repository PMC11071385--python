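"""Shrinkage covariance estimation with cross-validated intensity selection.

The shrinkage operator blends a sample covariance with its own diagonal,

    s(Sigma) = lambda * Sigma + (1 - lambda) * Sigma_diag,

where the shrinkage fraction ``lambda`` lies in [0, 1]: 1 preserves the
sample covariance, 0 zeroes every off-diagonal element.  The target keeps
the original sample variances on the diagonal ("diagonal, unequal
variance") so no bias is imposed on the per-unit variances.

The fraction is chosen by cross-validation: the data are split once into a
training set (~80%) and a testing set (~20%), the training covariance is
shrunk by each candidate fraction, and the fraction minimizing the mean
Gaussian negative log likelihood of the held-out observations is selected.
For noise estimation the split is over trials and held-out responses are
scored after removing each condition's mean (to remove the signal); for
data estimation the split is over conditions (rows of the trial-averaged
matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .data import (
    ResponseData,
    as_response_data,
    pooled_noise_covariance,
    sample_covariance,
    trial_average,
)

__all__ = [
    "ShrinkageFit",
    "InvalidCovarianceError",
    "default_fraction_grid",
    "apply_shrinkage",
    "gaussian_nll",
    "cv_select_shrinkage",
    "ShrunkCovarianceCV",
]


class InvalidCovarianceError(ValueError):
    """Candidate covariance is not symmetric positive definite."""


def default_fraction_grid() -> np.ndarray:
    """Candidate shrinkage fractions 0.00, 0.02, ..., 1.00 (51 values)."""
    return np.round(np.arange(51) * 0.02, 10)


def apply_shrinkage(cov: np.ndarray, fraction: float) -> np.ndarray:
    """Scale the off-diagonal elements of ``cov`` by ``fraction``,
    preserving the diagonal exactly."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {cov.shape}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"shrinkage fraction must be in [0, 1], got {fraction}")
    out = fraction * cov
    np.fill_diagonal(out, np.diag(cov))
    return out


def gaussian_nll(samples: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Mean per-sample negative log likelihood under a multivariate normal.

    Raises
    ------
    InvalidCovarianceError
        If the covariance is not positive definite; callers scoring
        shrinkage candidates treat this as an infinite NLL.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.asarray(cov, dtype=float)
    n = mean.size
    if samples.shape[1] != n or cov.shape != (n, n):
        raise ValueError("dimension mismatch between samples, mean and covariance")
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise InvalidCovarianceError("covariance is not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    dev = linalg.solve_triangular(chol, (samples - mean).T, lower=True)
    maha = float(np.mean(np.sum(dev * dev, axis=0)))
    return 0.5 * (n * math.log(2.0 * math.pi) + logdet + maha)


@dataclass
class ShrinkageFit:
    """Outcome of cross-validated shrinkage selection."""

    selected_fraction: float
    candidate_fractions: np.ndarray
    mean_nll_per_candidate: np.ndarray
    covariance: np.ndarray
    mode: str


def _train_size(m: int, leaveout_fraction: float) -> int:
    """ceil((1 - leaveout) * m), clipped so training has >= 2 samples and
    testing has >= 1."""
    n_train = math.ceil((1.0 - leaveout_fraction) * m)
    return int(min(max(n_train, 2), m - 1))


def _select(fractions: np.ndarray, nlls: np.ndarray) -> int:
    """Index of the minimum NLL; exact ties break toward the larger
    fraction (less shrinkage)."""
    best = np.min(nlls)
    if not np.isfinite(best):
        raise RuntimeError(
            "no shrinkage candidate produced a positive-definite covariance"
        )
    return int(np.max(np.flatnonzero(nlls == best)))


def cv_select_shrinkage(
    data,
    mode: str = "data",
    leaveout_fraction: float = 0.2,
    candidate_fractions=None,
    want_full: bool = True,
    random_state=None,
) -> ShrinkageFit:
    """Select a shrinkage fraction by a single random train/test split.

    Parameters
    ----------
    data : ndarray or ResponseData
        ``mode="data"``: a 2-D (samples x variables) matrix, or repeated
        trial data whose trial averages become the samples.
        ``mode="noise"``: repeated-trial data; the pooled per-condition
        trial covariance is the object being shrunk.
    mode : {"data", "noise"}
    leaveout_fraction : float
        Approximate fraction of samples held out for scoring.
    candidate_fractions : array-like, optional
        Defaults to 0, 0.02, ..., 1.
    want_full : bool
        Re-apply the selected fraction to the covariance of the full
        dataset (train + test); slightly more shrinkage than optimal but
        uses all the data.
    random_state : int, Generator, or None
        Controls the random split.
    """
    rng = np.random.default_rng(random_state)
    fractions = (
        default_fraction_grid()
        if candidate_fractions is None
        else np.sort(np.asarray(candidate_fractions, dtype=float))
    )
    if fractions.size == 0 or fractions[0] < 0 or fractions[-1] > 1:
        raise ValueError("candidate fractions must lie within [0, 1]")

    if mode == "data":
        if isinstance(data, ResponseData) or np.asarray(data).ndim == 3:
            rows = trial_average(data)
        else:
            rows = np.asarray(data, dtype=float)
            if rows.ndim != 2:
                raise ValueError("mode='data' expects a 2-D samples matrix")
        m = rows.shape[0]
        if m < 3:
            raise ValueError("need at least 3 samples to cross-validate")
        perm = rng.permutation(m)
        n_train = _train_size(m, leaveout_fraction)
        train, test = rows[perm[:n_train]], rows[perm[n_train:]]
        train_cov = sample_covariance(train)
        train_mean = train.mean(axis=0)
        nlls = _score_candidates(test, train_mean, train_cov, fractions)
        idx = _select(fractions, nlls)
        base = sample_covariance(rows) if want_full else train_cov
        final = apply_shrinkage(base, fractions[idx])
        return ShrinkageFit(float(fractions[idx]), fractions, nlls, final, mode)

    if mode == "noise":
        rd = as_response_data(data)
        n, c, t = rd.shape
        if t == 2:
            # a trial split cannot leave two training trials per condition;
            # fall back to holding out whole conditions instead
            perm = rng.permutation(c)
            n_train = _train_size(c, leaveout_fraction)
            train_vals = rd.values[:, perm[:n_train], :]
            test_vals = rd.values[:, perm[n_train:], :]
            train_cov = pooled_noise_covariance(ResponseData(train_vals))
            resid = test_vals - test_vals.mean(axis=2, keepdims=True)
            test_rows = resid.reshape(n, -1).T
        else:
            perm = rng.permutation(t)
            n_train = _train_size(t, leaveout_fraction)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            train_vals = rd.values[:, :, train_idx]
            test_vals = rd.values[:, :, test_idx]
            train_cov = pooled_noise_covariance(ResponseData(train_vals))
            if test_idx.size >= 2:
                center = test_vals.mean(axis=2, keepdims=True)
            else:
                # a single held-out trial per condition would be its own
                # mean (zero residuals); the training-trial mean removes
                # the shared signal draw without leaking the test data
                center = train_vals.mean(axis=2, keepdims=True)
            test_rows = (test_vals - center).reshape(n, -1).T
        zero = np.zeros(n)
        nlls = _score_candidates(test_rows, zero, train_cov, fractions)
        idx = _select(fractions, nlls)
        base = pooled_noise_covariance(rd) if want_full else train_cov
        final = apply_shrinkage(base, fractions[idx])
        return ShrinkageFit(float(fractions[idx]), fractions, nlls, final, mode)

    raise ValueError(f"unknown mode {mode!r}; expected 'data' or 'noise'")


def _score_candidates(test_rows, mean, train_cov, fractions) -> np.ndarray:
    nlls = np.empty(fractions.size)
    for k, f in enumerate(fractions):
        cand = apply_shrinkage(train_cov, f)
        try:
            nlls[k] = gaussian_nll(test_rows, mean, cand)
        except InvalidCovarianceError:
            nlls[k] = np.inf
    return nlls


class ShrunkCovarianceCV(BaseEstimator):
    """Covariance estimator with cross-validated diagonal shrinkage.

    Parameters
    ----------
    mode : {"data", "noise"}
        What the covariance describes; determines the split axis (see
        :func:`cv_select_shrinkage`).
    leaveout : float, default 0.2
    fractions : array-like, optional
        Candidate shrinkage fractions (default 0 to 1 in steps of 0.02).
    want_full : bool, default True
    random_state : int, Generator, or None

    Attributes
    ----------
    covariance_ : ndarray of shape (n, n)
    shrinkage_ : float
        Selected shrinkage fraction.
    fractions_ : ndarray
    nll_path_ : ndarray
        Mean held-out negative log likelihood per candidate.
    """

    def __init__(
        self,
        mode: str = "data",
        leaveout: float = 0.2,
        fractions=None,
        want_full: bool = True,
        random_state=None,
    ):
        self.mode = mode
        self.leaveout = leaveout
        self.fractions = fractions
        self.want_full = want_full
        self.random_state = random_state

    def fit(self, X, y=None):
        res = cv_select_shrinkage(
            X,
            mode=self.mode,
            leaveout_fraction=self.leaveout,
            candidate_fractions=self.fractions,
            want_full=self.want_full,
            random_state=self.random_state,
        )
        self.covariance_ = res.covariance
        self.shrinkage_ = res.selected_fraction
        self.fractions_ = res.candidate_fractions
        self.nll_path_ = res.mean_nll_per_candidate
        self.fit_result_ = res
        return self
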