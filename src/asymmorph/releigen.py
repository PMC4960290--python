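"""Relative eigenanalysis of one covariance structure against another.

Solving A v = lambda B v diagonalizes A in the metric defined by B: the
relative eigenvectors are the directions simultaneously conjugate in both
ellipsoids, and the log relative eigenvalues are congruence-invariant
coordinates for the discrepancy between the two matrices.  The natural
distance between covariance structures is sqrt(sum_i log² lambda_i); a
single-factor inflation moves a covariance matrix along a geodesic of this
metric, so successive inflations of the same factor add their lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DimensionError

__all__ = ["RelativeEigenResult", "relative_eigen", "covariance_distance"]


def _check_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionError(f"{name} must be square")
    scale = max(1.0, float(np.max(np.abs(M))))
    if not np.allclose(M, M.T, atol=1e-9 * scale):
        raise ValueError(f"{name} is not symmetric to tolerance 1e-9")
    return (M + M.T) / 2.0


@dataclass
class RelativeEigenResult:
    """Eigenvalues (descending), B-orthonormal eigenvectors (columns), and
    the log-eigenvalue distance sqrt(sum log² lambda).  ``null_rank`` counts
    zero relative eigenvalues (PSD A); the distance is +inf in that case."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    distance: float
    null_rank: int = 0


def relative_eigen(A: np.ndarray, B: np.ndarray, psd_tol: float = 1e-10) -> RelativeEigenResult:
    """Solve A v = lambda B v for SPD B (A may be PSD).

    Computed by Cholesky whitening of B followed by a symmetric eigensolve,
    which is stabler than a direct generalized solver when B is
    ill-conditioned.  Eigenvalues are invariant under the joint congruence
    A -> M A M^T, B -> M B M^T for any invertible M.
    """
    A = _check_symmetric(A, "A")
    B = _check_symmetric(B, "B")
    if A.shape != B.shape:
        raise DimensionError("A and B must have the same order")
    try:
        L = np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        evals = np.linalg.eigvalsh(B)
        null = [i for i, e in enumerate(evals) if e <= 0]
        raise ValueError(
            f"B is not positive definite (eigenvalues {evals[null]} at positions {null})"
        ) from None
    W = scipy.linalg.solve_triangular(L, A, lower=True)
    W = scipy.linalg.solve_triangular(L, W.T, lower=True).T
    W = (W + W.T) / 2.0
    lam, U = np.linalg.eigh(W)
    lam, U = lam[::-1], U[:, ::-1]
    V = scipy.linalg.solve_triangular(L.T, U, lower=False)
    # sign canonicalization: largest-magnitude coordinate positive
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    scale = max(float(lam[0]), 1.0) if lam.size else 1.0
    null_rank = int(np.sum(lam <= psd_tol * scale))
    if null_rank:
        distance = float("inf")
    else:
        distance = float(np.sqrt(np.sum(np.log(lam) ** 2)))
    return RelativeEigenResult(lam, V, distance, null_rank)


def covariance_distance(A: np.ndarray, B: np.ndarray) -> float:
    """sqrt(sum_i log² lambda_i) over the relative eigenvalues of (A, B).

    Symmetric in its arguments, zero iff A = B, and invariant under joint
    congruence; +inf when A is rank-deficient relative to B.
    """
    return relative_eigen(A, B).distance
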