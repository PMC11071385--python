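"""Eigenspectrum analytics: PCA via eigendecomposition, effective
dimensionality, power-law line fitting, score projection, sign-alignment
conventions, and reliability/consistency metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import as_response_data, naive_estimates

__all__ = [
    "Eigenspectrum",
    "eigendecompose",
    "effective_dimensionality",
    "fit_power_law",
    "project_scores",
    "align_pc_signs",
    "splithalf_pc_reliability",
    "cross_subject_consistency",
]


@dataclass
class Eigenspectrum:
    """Nonincreasing eigenvalues with (optionally) matched orthonormal
    eigenvectors in the columns of ``eigenvectors``."""

    eigenvalues: np.ndarray
    eigenvectors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted in nonincreasing order")
        if self.eigenvectors is not None:
            self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
            V = self.eigenvectors
            if V.shape[1] != self.eigenvalues.size:
                raise ValueError("eigenvector columns must match eigenvalues")
            if np.max(np.abs(V.T @ V - np.eye(V.shape[1]))) > 1e-8:
                raise ValueError("eigenvectors are not orthonormal")


def eigendecompose(cov: np.ndarray) -> Eigenspectrum:
    """Eigendecomposition of a symmetric matrix, eigenvalues descending.

    Principal components are the eigenvector columns; the reconstruction
    ``V S V^T`` matches the input to within numerical precision.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {cov.shape}")
    scale = max(float(np.max(np.abs(cov))), 1.0)
    if np.max(np.abs(cov - cov.T)) > 1e-10 * scale:
        raise ValueError("matrix is not symmetric")
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    order = np.argsort(w)[::-1]
    return Eigenspectrum(w[order], V[:, order])


def effective_dimensionality(eigenvalues) -> float:
    """Effective dimensionality ``(sum lambda)^2 / sum lambda^2``.

    Ranges continuously from 1 (all variance in one dimension) to n (equal
    variance in every dimension) for nonnegative spectra, and is invariant
    to rescaling the spectrum.
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    ss = float(np.sum(lam**2))
    if ss == 0.0:
        raise ValueError("all-zero eigenspectrum has no dimensionality")
    return float(np.sum(lam)) ** 2 / ss


def fit_power_law(eigenvalues) -> tuple[float, float, np.ndarray]:
    """Fit a line to an eigenspectrum in log-log space.

    A heuristic keeps the fit robust across diverse spectra: sampling
    indices come from a linear grid in log space from log(1) to log(d)
    (granularity at least as fine as log(d) - log(d-1)), mapped back and
    rounded to integers so no interpolation of eigenvalues is needed; only
    "good" eigenvalues — greater than 0.001 of the maximum — enter the fit
    (the threshold scale is divided by 10 until at least two eigenvalues
    qualify).  Returns ``(slope, intercept, used_indices)`` of the
    least-squares line through (log index, log eigenvalue); the power-law
    exponent is ``-slope``.
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    d = lam.size
    if d < 2:
        raise ValueError("need at least two eigenvalues")
    lam_max = float(np.max(lam))
    if lam_max <= 0:
        raise ValueError("maximum eigenvalue must be positive")
    if np.sum(lam > 0) < 2:
        raise ValueError("need at least two positive eigenvalues to fit")

    log_d = np.log(d)
    spacing = log_d - np.log(d - 1)
    n_grid = max(d, int(np.ceil(log_d / spacing)) + 1)
    grid = np.exp(np.linspace(0.0, log_d, n_grid))
    indices = np.unique(np.clip(np.rint(grid).astype(int), 1, d))

    scale = 0.001
    good = lam > scale * lam_max
    while np.sum(good) < 2:
        scale /= 10.0
        good = lam > scale * lam_max
        if scale < 1e-300:  # pragma: no cover - guarded by the >=2 positive check
            raise ValueError("could not find two good eigenvalues")

    used = indices[good[indices - 1]]
    x = np.log(used.astype(float))
    y = np.log(lam[used - 1])
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), used


def project_scores(rows: np.ndarray, centroid: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Scores of data points relative to a centroid in the basis of the
    given principal components: ``(rows - centroid) @ components``."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    centroid = np.asarray(centroid, dtype=float).ravel()
    components = np.asarray(components, dtype=float)
    if rows.shape[1] != centroid.size or components.shape[0] != centroid.size:
        raise ValueError("shape mismatch between rows, centroid and components")
    return (rows - centroid) @ components


def align_pc_signs(components: np.ndarray, partner: Optional[np.ndarray] = None):
    """Resolve the sign ambiguity of principal components.

    Stage 1: flip any column whose mean is negative (zero-mean columns are
    left unchanged).  Stage 2 (when ``partner`` is given): after stage 1 on
    both, flip columns of the *partner* so their cosine similarity with the
    corresponding reference column is non-negative.  Returns the aligned
    matrix, or ``(reference, partner)`` when a partner is supplied.
    """
    comp = np.array(components, dtype=float, copy=True)
    means = comp.mean(axis=0)
    comp[:, means < 0] *= -1.0
    if partner is None:
        return comp
    part = np.array(partner, dtype=float, copy=True)
    if part.shape[1] != comp.shape[1]:
        raise ValueError("partner must have the same number of columns")
    pmeans = part.mean(axis=0)
    part[:, pmeans < 0] *= -1.0
    sims = np.einsum("ij,ij->j", comp, part)
    part[:, sims < 0] *= -1.0
    return comp, part


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b) / (na * nb)


_RELIABILITY_ESTIMATORS = ("gsn-signal", "gsn-noise", "naive")


def splithalf_pc_reliability(
    data, estimator: str = "gsn-signal", random_state=None, **fit_kwargs
) -> np.ndarray:
    """Cosine similarity of principal components across condition halves.

    Conditions are split into two random halves, the chosen covariance
    estimator ("gsn-signal", "gsn-noise", or "naive" trial-averaged signal)
    is fit on each half, and the sign-aligned eigenvectors are compared
    dimension by dimension.  Reliable structure yields leading cosines near
    1; pure noise yields cosines near 0.
    """
    from .gsn import GSN  # local import to avoid a cycle

    if estimator not in _RELIABILITY_ESTIMATORS:
        raise ValueError(
            f"unknown estimator {estimator!r}; expected one of "
            f"{_RELIABILITY_ESTIMATORS}"
        )
    rd = as_response_data(data)
    n, c, t = rd.shape
    if c < 4:
        raise ValueError("need at least 4 conditions to split into halves")
    rng = np.random.default_rng(random_state)
    perm = rng.permutation(c)
    halves = (perm[: c // 2], perm[c // 2 :])

    spectra = []
    for sel in halves:
        vals = rd.values[:, np.sort(sel), :]
        if estimator == "naive":
            cov = naive_estimates(vals)[0]
        else:
            fit = GSN(random_state=rng, **fit_kwargs).fit(vals)
            cov = fit.signal_cov_ if estimator == "gsn-signal" else fit.noise_cov_
        spectra.append(eigendecompose(cov))

    k = min(n, min(len(h) for h in halves) - 1)
    V1, V2 = align_pc_signs(
        spectra[0].eigenvectors[:, :k], spectra[1].eigenvectors[:, :k]
    )
    return np.einsum("ij,ij->j", V1, V2)


def cross_subject_consistency(score_vectors, max_iter: int = 100) -> np.ndarray:
    """Pairwise cosine similarity of per-subject score vectors after
    iterative sign alignment.

    Each subject's vector is flipped, repeatedly, whenever its cosine with
    the average of the other subjects' vectors is negative, until stable or
    ``max_iter`` sweeps.  Returns the symmetric cosine matrix (unit
    diagonal).
    """
    vecs = [np.asarray(v, dtype=float).ravel() for v in score_vectors]
    if len(vecs) < 2:
        raise ValueError("need at least two subjects")
    length = vecs[0].size
    if any(v.size != length for v in vecs):
        raise ValueError("score vectors must have equal length")
    if any(np.linalg.norm(v) == 0.0 for v in vecs):
        raise ValueError("zero score vector supplied")

    V = np.stack(vecs)
    m = V.shape[0]
    for _ in range(max_iter):
        flipped = False
        for i in range(m):
            others = (V.sum(axis=0) - V[i]) / (m - 1)
            if np.linalg.norm(others) == 0.0:
                continue
            if _cosine(V[i], others) < 0:
                V[i] *= -1.0
                flipped = True
        if not flipped:
            break

    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = _cosine(V[i], V[j])
    return out
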