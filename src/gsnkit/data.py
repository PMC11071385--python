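"""Core data model and covariance primitives.

The package-wide axis convention for repeated-trial measurements is
``(unit, condition, trial)``: an array of shape ``(n, c, t)`` holds the
response of ``n`` measured channels (voxels, vertices, neurons, electrodes)
to ``c`` experimental conditions, each repeated for ``t`` trials.  All
estimators in this package assume complete trial blocks (no missing values)
and at least two trials per condition, since a single trial cannot separate
trial-to-trial variability from the condition's mean response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ResponseData",
    "GaussianMoments",
    "as_response_data",
    "trial_average",
    "sample_covariance",
    "pooled_noise_covariance",
    "naive_estimates",
    "covariance_to_correlation",
    "zscore_units",
]


@dataclass
class ResponseData:
    """Repeated-trial multivariate measurements.

    Parameters
    ----------
    values : ndarray of shape (n_units, n_conditions, n_trials)
        Response measurements.  Must be finite, with at least two
        conditions and at least two trials.
    unit_labels, condition_labels : sequence, optional
        Identifiers carried along for I/O and reporting.
    """

    values: np.ndarray
    unit_labels: Optional[Sequence] = None
    condition_labels: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3-D (unit, condition, trial) array, got shape "
                f"{self.values.shape}"
            )
        n, c, t = self.values.shape
        if n < 1:
            raise ValueError("need at least one unit")
        if c < 2:
            raise ValueError(f"need at least two conditions, got c={c}")
        if t < 2:
            raise ValueError(
                f"need at least two trials per condition (t > 1), got t={t}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at (unit, condition, trial)={tuple(bad)}"
            )
        if self.unit_labels is not None and len(self.unit_labels) != n:
            raise ValueError("unit_labels length does not match number of units")
        if self.condition_labels is not None and len(self.condition_labels) != c:
            raise ValueError(
                "condition_labels length does not match number of conditions"
            )

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class GaussianMoments:
    """First two moments (mean vector and covariance matrix) of one
    distribution: signal, noise, or trial-averaged data."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        n = self.mean.size
        if self.covariance.shape != (n, n):
            raise ValueError(
                f"covariance shape {self.covariance.shape} does not match "
                f"mean length {n}"
            )
        scale = max(float(np.max(np.abs(self.covariance))), 1.0)
        if np.max(np.abs(self.covariance - self.covariance.T)) > 1e-10 * scale:
            raise ValueError("covariance is not symmetric")

    @property
    def n_units(self) -> int:
        return self.mean.size


def as_response_data(data) -> ResponseData:
    """Coerce a raw 3-D array to :class:`ResponseData` (pass-through if
    already one)."""
    if isinstance(data, ResponseData):
        return data
    return ResponseData(np.asarray(data, dtype=float))


def trial_average(data) -> np.ndarray:
    """Average responses over trials.

    Returns the ``(c, n)`` matrix whose row ``j`` is the mean over trials of
    every unit's response to condition ``j``.  Trial averaging attenuates
    the noise covariance by ``1/t`` but does not remove it.
    """
    data = as_response_data(data)
    return data.values.mean(axis=2).T


def sample_covariance(samples: np.ndarray) -> np.ndarray:
    """Bessel-corrected sample covariance of row observations.

    ``cov(A) = Adot^T Adot / (d - 1)`` where ``Adot`` is ``A`` with its
    columns centered around zero and ``d`` the number of rows.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D (observations x variables) matrix")
    d = samples.shape[0]
    if d < 2:
        raise ValueError(f"need at least 2 observations, got {d}")
    centered = samples - samples.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / (d - 1)
    return 0.5 * (cov + cov.T)


def pooled_noise_covariance(data) -> np.ndarray:
    """Trial-to-trial covariance pooled over conditions.

    Computes the sample covariance of the ``t`` trials separately for every
    condition and averages the ``c`` per-condition covariances.  This is an
    unbiased estimator of the noise covariance under the additive
    signal-plus-noise model.
    """
    data = as_response_data(data)
    n, c, t = data.shape
    # residuals around each condition's own trial mean; einsum pools the
    # per-condition cross-products without a Python loop over conditions
    resid = data.values - data.values.mean(axis=2, keepdims=True)
    cov = np.einsum("ict,jct->ij", resid, resid) / (c * (t - 1))
    return 0.5 * (cov + cov.T)


def naive_estimates(data) -> tuple[np.ndarray, np.ndarray]:
    """Heuristic signal and noise covariance estimates.

    The naive signal estimate is the sample covariance of trial-averaged
    responses; it is biased upward by the residual noise, with expectation
    ``Sigma_signal + Sigma_noise / t``.  The naive noise estimate demeans
    responses within each condition, aggregates all ``c*t`` residuals, and
    divides by ``c*t - 1``; the inflated denominator (the correct pooled
    denominator is ``c*(t-1)``) biases it downward by the factor
    ``c*(t-1)/(c*t-1)``.
    """
    data = as_response_data(data)
    n, c, t = data.shape
    signal_cov = sample_covariance(trial_average(data))
    resid = data.values - data.values.mean(axis=2, keepdims=True)
    rows = resid.reshape(n, c * t).T
    # per-condition residuals already sum to zero, so this extra centering
    # is a numerical no-op kept for symmetry with sample_covariance
    rows = rows - rows.mean(axis=0, keepdims=True)
    noise_cov = rows.T @ rows / (c * t - 1)
    return signal_cov, 0.5 * (noise_cov + noise_cov.T)


def covariance_to_correlation(cov: np.ndarray) -> np.ndarray:
    """Convert a covariance matrix to correlation units.

    Each element is divided by the square roots of its row- and
    column-associated diagonal elements.
    """
    cov = np.asarray(cov, dtype=float)
    d = np.diag(cov)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive variance on the diagonal for unit(s) {bad.tolist()}; "
            "cannot convert to correlation"
        )
    s = np.sqrt(d)
    return cov / np.outer(s, s)


def zscore_units(data, groups=None):
    """Standardize each unit to zero mean and unit (Bessel-corrected)
    variance, optionally within groups of samples.

    For a 2-D ``(samples, units)`` matrix, ``groups`` is a label per row;
    for :class:`ResponseData`, ``groups`` is a label per condition (all
    trials of a condition belong to the same group, e.g. a scan session).
    Default is a single group.
    """
    if isinstance(data, ResponseData) or (
        hasattr(data, "ndim") and np.asarray(data).ndim == 3
    ):
        rd = as_response_data(data)
        n, c, t = rd.shape
        glabels = np.zeros(c, dtype=int) if groups is None else np.asarray(groups)
        if glabels.shape != (c,):
            raise ValueError("groups must supply one label per condition")
        out = rd.values.copy()
        for g in np.unique(glabels):
            sel = glabels == g
            block = out[:, sel, :].reshape(n, -1)
            out[:, sel, :] = _zscore_rows(block).reshape(n, int(sel.sum()), t)
        return ResponseData(out, rd.unit_labels, rd.condition_labels)

    mat = np.asarray(data, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D matrix or 3-D ResponseData")
    glabels = (
        np.zeros(mat.shape[0], dtype=int) if groups is None else np.asarray(groups)
    )
    if glabels.shape != (mat.shape[0],):
        raise ValueError("groups must supply one label per sample (row)")
    out = mat.copy()
    for g in np.unique(glabels):
        sel = glabels == g
        out[sel] = _zscore_rows(mat[sel].T).T
    return out


def _zscore_rows(block: np.ndarray) -> np.ndarray:
    """Z-score each row of a (units, samples) block."""
    if block.shape[1] < 2:
        raise ValueError("need at least two samples per group to z-score")
    mean = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"zero variance for unit(s) {bad.tolist()}; cannot z-score")
    return (block - mean) / sd
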