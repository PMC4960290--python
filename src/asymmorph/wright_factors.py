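"""Wright's general/special factor decomposition of a correlation matrix.

Where principal components of an all-positive correlation matrix force
every component after the first to mix signs (Perron-Frobenius), Wright's
path-analytic decomposition models only the off-diagonal of R as

    R_offdiagonal ~ g ⊗ g + s_1 ⊗ s_1 + ... + s_m ⊗ s_m

with one nonnegative general factor g loading every variable and one
special factor per block of variables (e.g. skull, forelimb, hindlimb),
constant within its block and zero outside.  The loadings then read as
path coefficients of biologically distinct growth processes rather than as
orthogonality-driven contrasts.

Estimation here is alternating least squares for g on the cross-block
off-diagonal cells (which the specials never touch), followed by moment
matching of each block's shared special loading to the mean within-block
residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DimensionError, StructuralError
from .io_landmarks import SquareMatrixInput

__all__ = ["WrightFactorModel", "pca_reference", "fit_wright", "factor_scores"]


def pca_reference(R: SquareMatrixInput, n_components: int | None = None):
    """Descending eigenvalues and unit eigenvectors of a symmetric matrix.

    Eigenvectors are sign-canonicalized so each one's mean loading is
    nonnegative; for an all-positive matrix the first is then all-positive.
    Returns (eigenvalues, loadings) with loadings in columns.
    """
    vals, vecs = np.linalg.eigh(R.values)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    means = vecs.mean(axis=0)
    signs = np.where(means < 0, -1.0, 1.0)
    vecs = vecs * signs
    if n_components is not None:
        vals, vecs = vals[:n_components], vecs[:, :n_components]
    return vals, vecs


@dataclass
class WrightFactorModel:
    """One general factor plus block-shared special factors.

    ``fitted`` is g⊗g + sum s_i⊗s_i with the observed diagonal restored for
    readability; ``residual`` is the off-diagonal residual (diagonal zero).
    Blocks may be singletons, which contribute no special factor.
    """

    g: np.ndarray
    specials: list[tuple[tuple[int, ...], float]]
    blocks: list[tuple[int, ...]]
    fitted: np.ndarray
    residual: np.ndarray
    rms_residual: float
    variable_names: list[str]
    n_iterations: int

    def special_vector(self, i: int) -> np.ndarray:
        block, loading = self.specials[i]
        s = np.zeros_like(self.g)
        s[list(block)] = loading
        return s


def _block_masks(p: int, blocks: Sequence[Sequence[int]]) -> np.ndarray:
    membership = np.full(p, -1, dtype=int)
    for b, block in enumerate(blocks):
        for i in block:
            if not (0 <= i < p):
                raise StructuralError(f"block index {i} out of range for p={p}")
            if membership[i] != -1:
                raise StructuralError(f"variable {i} appears in two blocks")
            membership[i] = b
    if np.any(membership == -1):
        missing = np.flatnonzero(membership == -1).tolist()
        raise StructuralError(f"variables {missing} belong to no block")
    return membership


def fit_wright(
    R: SquareMatrixInput,
    blocks: Sequence[Sequence[int]],
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> WrightFactorModel:
    """Fit the one-general/several-special decomposition.

    g minimizes the sum of squared residuals over cross-block off-diagonal
    cells (a rank-1 fit by alternating least squares, initialized at the
    square roots of the row means of those cells); each block's shared
    special loading is then the square root of the mean within-block
    off-diagonal residual, clamped at zero (with a warning) if that mean is
    negative.
    """
    A = R.values
    p = R.p
    if p < 3:
        raise StructuralError("fit_wright requires p >= 3 variables")
    membership = _block_masks(p, blocks)
    cross = membership[:, None] != membership[None, :]
    if np.any(cross.sum(axis=1) == 0):
        lonely = np.flatnonzero(cross.sum(axis=1) == 0).tolist()
        raise StructuralError(
            f"variables {lonely} have no cross-block cell: g not identifiable"
        )
    row_means = np.array([A[i, cross[i]].mean() for i in range(p)])
    g = np.sqrt(np.clip(row_means, 1e-12, None))
    it = 0
    for it in range(1, max_iter + 1):
        delta = 0.0
        for i in range(p):  # coordinate descent: each update is the exact
            m = cross[i]  # 1-D least-squares optimum, so the fit is monotone
            denom = float(g[m] @ g[m])
            gi = float(A[i, m] @ g[m]) / denom if denom > 0 else 0.0
            delta = max(delta, abs(gi - g[i]))
            g[i] = gi
        if delta < tol:
            break
    g = np.clip(g, 0.0, None)
    resid = A - np.outer(g, g)
    specials: list[tuple[tuple[int, ...], float]] = []
    for block in blocks:
        idx = tuple(int(i) for i in block)
        if len(idx) < 2:
            continue
        sub = resid[np.ix_(idx, idx)]
        off = sub[~np.eye(len(idx), dtype=bool)]
        mean_resid = float(off.mean())
        if mean_resid < 0:
            warnings.warn(
                f"block {idx}: negative mean within-block residual "
                f"({mean_resid:.4f}); special loading clamped at 0"
            )
            loading = 0.0
        else:
            loading = float(np.sqrt(mean_resid))
        specials.append((idx, loading))
    fitted = np.outer(g, g)
    for idx, loading in specials:
        s = np.zeros(p)
        s[list(idx)] = loading
        fitted += np.outer(s, s)
    np.fill_diagonal(fitted, np.diag(A))
    residual = A - fitted
    np.fill_diagonal(residual, 0.0)
    offmask = ~np.eye(p, dtype=bool)
    rms = float(np.sqrt(np.mean(residual[offmask] ** 2)))
    return WrightFactorModel(
        g=g,
        specials=specials,
        blocks=[tuple(int(i) for i in b) for b in blocks],
        fitted=fitted,
        residual=residual,
        rms_residual=rms,
        variable_names=list(R.variable_names),
        n_iterations=it,
    )


def factor_scores(
    model: WrightFactorModel, data: np.ndarray, unit_variance: bool = False
) -> np.ndarray:
    """Estimate each specimen's general-factor value.

    ``data`` must be n × p, standardized per variable in the same variable
    order as the fitted matrix.  The score is the g-weighted combination
    data · g / ||g||²; with ``unit_variance`` the scores are rescaled to
    unit sample variance.
    """
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[1] != model.g.size:
        raise DimensionError(
            f"data must be n×{model.g.size} (variable order of the fitted matrix)"
        )
    scores = data @ model.g / float(model.g @ model.g)
    if unit_variance:
        sd = scores.std(ddof=1)
        if sd > 0:
            scores = scores / sd
    return scores
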