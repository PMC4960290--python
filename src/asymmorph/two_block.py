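"""Cross-block association statistics.

Three tools for relating two blocks of variables measured on the same
specimens.  The RV coefficient is implemented primarily to demonstrate its
troublesome symmetry: it is invariant under arbitrary separate rotations of
either block, so it cannot distinguish biologically different cross-block
patterns that happen to share the same net covariance magnitude.  The
recommended alternative is a singular-value decomposition of the
cross-covariance matrix S_XY itself, whose individual axis pairs can be
inspected and interpreted.  The third tool is the Mantel-style regression of
one pairwise distance on another: a single through-origin slope
sum(d1·d2)/sum(d1²), playing the role of a diffusion constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError

__all__ = ["TwoBlockData", "rv_coefficient", "pls_svd", "PLSResult", "distance_regression"]


@dataclass
class TwoBlockData:
    """Two blocks of columns over the same n specimens."""

    X: np.ndarray
    Y: np.ndarray
    x_names: list[str] | None = None
    y_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.Y = np.atleast_2d(np.asarray(self.Y, float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise DimensionError("X and Y must have the same number of rows")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("non-finite values in a block")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _cov_blocks(data: TwoBlockData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample covariance blocks with the n-1 denominator."""
    if data.n < 3:
        raise ValueError("n >= 3 specimens required")
    Xc = data.X - data.X.mean(axis=0)
    Yc = data.Y - data.Y.mean(axis=0)
    f = 1.0 / (data.n - 1)
    return f * Xc.T @ Xc, f * Yc.T @ Yc, f * Xc.T @ Yc


def rv_coefficient(data: TwoBlockData) -> float:
    """Escoufier's RV: tr(S_XY S_YX) / sqrt(tr(S_XX²) · tr(S_YY²)).

    A scalar in [0, 1], equal to 1 when Y is X (or any rotation of it) —
    the separate-rotation invariance is exactly the property that makes the
    statistic a poor carrier of biological meaning, and is asserted in this
    package's tests rather than hidden.
    """
    Sxx, Syy, Sxy = _cov_blocks(data)
    den = np.sqrt(np.sum(Sxx**2) * np.sum(Syy**2))
    if den <= 0:
        raise ValueError("zero-variance block: RV undefined")
    return float(np.sum(Sxy**2) / den)


@dataclass
class PLSResult:
    """SVD structure of the cross-covariance matrix S_XY.

    Per pair i: singular value d_i (the covariance of the paired scores),
    unit axes u_i (X side) and v_i (Y side), and the score vectors X·u_i,
    Y·v_i (computed on centered blocks).
    """

    singular_values: np.ndarray
    x_axes: np.ndarray  # p × n_pairs, columns unit
    y_axes: np.ndarray  # q × n_pairs
    x_scores: np.ndarray
    y_scores: np.ndarray


def pls_svd(data: TwoBlockData, n_pairs: int | None = None) -> PLSResult:
    """Two-block partial least squares: SVD of S_XY.

    The covariance of the i-th score pair equals the i-th singular value,
    and the squared singular values sum to tr(S_XY S_YX) — the numerator the
    RV coefficient collapses into one number.
    """
    _, _, Sxy = _cov_blocks(data)
    pq = min(Sxy.shape)
    if n_pairs is None:
        n_pairs = pq
    if not (1 <= n_pairs <= pq):
        raise ValueError(f"n_pairs must be in 1..{pq}")
    u, s, vt = np.linalg.svd(Sxy, full_matrices=False)
    u, s, v = u[:, :n_pairs], s[:n_pairs], vt[:n_pairs].T
    # canonical sign: largest-magnitude X loading positive
    for i in range(n_pairs):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            v[:, i] = -v[:, i]
    Xc = data.X - data.X.mean(axis=0)
    Yc = data.Y - data.Y.mean(axis=0)
    return PLSResult(s, u, v, Xc @ u, Yc @ v)


def distance_regression(d1: np.ndarray, d2: np.ndarray) -> float:
    """Through-origin regression slope of one distance set on another:
    sum(d1·d2) / sum(d1²).

    Accepts either flattened pair vectors (each unordered pair once) or full
    square distance matrices, whose diagonals are omitted and whose upper
    triangles are used once.  No intercept: zero distance must map to zero
    distance.
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    if d1.shape != d2.shape:
        raise DimensionError("distance sets must have matching shapes")
    if d1.ndim == 2:
        if d1.shape[0] != d1.shape[1]:
            raise DimensionError("distance matrices must be square")
        iu = np.triu_indices(d1.shape[0], k=1)
        d1, d2 = d1[iu], d2[iu]
    denom = float(d1 @ d1)
    if denom <= 0:
        raise ValueError("all d1 distances are zero: slope undefined")
    return float(d1 @ d2) / denom
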