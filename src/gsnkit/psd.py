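"""Nearest symmetric positive semi-definite (PSD) matrix projection.

Covariance estimates formed by subtraction can leave the PSD cone.  The
projection implemented here finds the Frobenius-nearest symmetric PSD
matrix (Higham's method): symmetrize, then average the matrix with its
symmetric polar factor obtained from an SVD.  For a symmetric input this is
equivalent to eigendecomposing and clipping negative eigenvalues to zero.
Because the PSD cone is convex, projecting an estimate onto it can only
reduce its distance to any true (PSD) covariance matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nearest_psd", "is_psd", "min_eigenvalue_tolerance"]

#: jitter added to the diagonal when numerical round-off leaves the
#: reconstruction indefinite
EPSILON = 1e-10

#: bounded number of jitter-and-retry passes
MAX_RESTARTS = 100


def min_eigenvalue_tolerance(matrix: np.ndarray) -> float:
    """Negative slack allowed on the minimum eigenvalue of a nominally PSD
    matrix: ``1e-10 * max(largest eigenvalue magnitude, 1)``."""
    matrix = np.asarray(matrix, dtype=float)
    scale = max(float(np.max(np.abs(matrix))), 1.0) if matrix.size else 1.0
    return 1e-10 * scale


def is_psd(matrix: np.ndarray, tol: float | None = None) -> bool:
    """Whether a symmetric matrix is PSD up to numerical tolerance."""
    matrix = np.asarray(matrix, dtype=float)
    if tol is None:
        tol = min_eigenvalue_tolerance(matrix)
    eigvals = np.linalg.eigvalsh(0.5 * (matrix + matrix.T))
    return bool(eigvals[0] >= -tol)


def nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Project a square matrix onto the cone of symmetric PSD matrices.

    Steps: (1) symmetrize ``C <- (C + C^T)/2``; (2) SVD ``C = U S V^T``;
    (3) form ``(C + V S V^T)/2``; (4) if round-off leaves the result
    indefinite, add ``1e-10 * I`` and repeat from (2).  Retries are capped;
    exceeding the cap raises rather than silently returning an indefinite
    matrix.
    """
    C = np.asarray(matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {C.shape}")
    if not np.all(np.isfinite(C)):
        raise ValueError("matrix contains non-finite entries")

    C = 0.5 * (C + C.T)
    for _ in range(MAX_RESTARTS):
        _, S, Vt = np.linalg.svd(C)
        H = Vt.T @ (S[:, None] * Vt)  # symmetric polar factor V S V^T
        C_hat = 0.5 * (C + H)
        C_hat = 0.5 * (C_hat + C_hat.T)
        if is_psd(C_hat):
            return C_hat
        C = C_hat + EPSILON * np.eye(C.shape[0])
    raise RuntimeError(
        f"nearest_psd failed to produce a PSD matrix after {MAX_RESTARTS} "
        "jitter restarts"
    )
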