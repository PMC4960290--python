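"""Thin-plate spline bending energy, partial warps, deformation grids.

The bending-energy matrix is the quadratic form, on per-landmark
displacements of a mean configuration, of the integrated squared second
derivatives of the interpolating thin-plate spline.  Its null space is
exactly the affine fields (dimension 3 in 2D); its positive eigenvectors are
the partial warps, ordered here by ascending eigenvalue so that the
largest-scale (least bent) warp comes first.

Kernel convention: U(r) = r² log r.  A different constant factor in the
kernel rescales all eigenvalues jointly, shifting log bending energy by a
constant and leaving every BE-PWV slope unchanged; eigenvalues from another
implementation using U(r) = r² log r² are exactly twice ours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError, DimensionError
from .io_landmarks import LandmarkConfiguration
from .procrustes import MeanFormWithJ, project_to_shape_space

__all__ = [
    "PartialWarpBasis",
    "bending_energy_matrix",
    "partial_warp_basis",
    "tps_grid",
]

_ZERO_EIG_RTOL = 1e-9


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, with U(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def bending_energy_matrix(ref: MeanFormWithJ) -> np.ndarray:
    """k×k bending-energy matrix of the thin-plate spline on the mean form.

    Built as the upper-left k×k block of the inverse of the bordered system
    [[K, Q], [Q^T, 0]] with K_ij = U(|p_i - p_j|) and Q = [1 | x | y].
    Positive semidefinite with rank k-3 in 2D; affine displacement fields
    are annihilated exactly.
    """
    pts = ref.coords
    k = pts.shape[0]
    if k < 4:
        raise DegeneracyError("bending energy requires k >= 4 landmarks in 2D")
    r = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if np.min(r + np.eye(k)) < 1e-12:
        raise DegeneracyError("coincident landmarks: singular TPS kernel")
    K = _tps_kernel(r)
    Q = np.column_stack([np.ones(k), pts])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError:
        raise DegeneracyError("singular bordered TPS system") from None
    be = Linv[:k, :k]
    return (be + be.T) / 2.0


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip sign so the largest-magnitude coordinate is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


@dataclass
class PartialWarpBasis:
    """Eigenstructure of a mean form's bending energy.

    ``eigenvalues`` are the k-3 positive eigenvalues, ascending (the first
    warp is the largest-scale one).  ``warp_vectors`` holds the matching
    k-vectors as rows.  ``shape_directions(axis)`` lifts warp j to a 2k
    shape-space direction by placing its k-vector on one Cartesian axis;
    these lifted directions are automatically orthogonal to all rows of J.
    ``uniform_basis`` (2×2k, orthonormal rows) spans the affine shape
    variation left after the J-projection — the zero-bending-energy
    directions of shape space.
    """

    be_matrix: np.ndarray
    eigenvalues: np.ndarray
    warp_vectors: np.ndarray
    uniform_basis: np.ndarray
    reference: MeanFormWithJ
    tied: bool = False

    @property
    def n_warps(self) -> int:
        return self.eigenvalues.size

    def shape_directions(self) -> np.ndarray:
        """(2·n_warps) × 2k matrix: warp j on the x-axis then on the y-axis,
        grouped per warp (rows 2j, 2j+1)."""
        k = self.reference.k
        out = np.zeros((2 * self.n_warps, 2 * k))
        out[0::2, 0::2] = self.warp_vectors
        out[1::2, 1::2] = self.warp_vectors
        return out


def partial_warp_basis(ref: MeanFormWithJ) -> PartialWarpBasis:
    """Eigendecompose the bending energy and the uniform (affine) subspace."""
    be = bending_energy_matrix(ref)
    evals, evecs = np.linalg.eigh(be)
    tol = _ZERO_EIG_RTOL * float(evals[-1])
    pos = evals > tol
    n_zero = int(np.sum(~pos))
    if n_zero != 3:
        raise DegeneracyError(
            f"bending energy has {n_zero} zero eigenvalues (expected 3 in 2D)"
        )
    lam = evals[pos]
    vecs = evecs[:, pos].T  # ascending with evals
    # deterministic basis under eigenvalue ties: within a tied group, sort by
    # the sign-canonicalized coordinate string
    tied = False
    i = 0
    order = np.arange(lam.size)
    while i < lam.size:
        j = i + 1
        while j < lam.size and (lam[j] - lam[i]) <= 1e-9 * lam[j]:
            j += 1
        if j - i > 1:
            tied = True
            group = sorted(
                range(i, j),
                key=lambda m: tuple(np.round(_canonical_sign(vecs[m]), 10)),
            )
            order[i:j] = group
        i = j
    vecs = np.array([_canonical_sign(vecs[m]) for m in order])
    lam = lam[order]

    # uniform basis: affine fields, J-projected, orthonormalized
    x, y = ref.mu[0::2], ref.mu[1::2]
    k = ref.k
    fields = np.zeros((4, 2 * k))
    fields[0, 0::2] = x
    fields[1, 0::2] = y
    fields[2, 1::2] = x
    fields[3, 1::2] = y
    proj = project_to_shape_space(fields, ref)
    u, s, vt = np.linalg.svd(proj, full_matrices=False)
    nz = s > 1e-10 * s[0]
    uniform = vt[nz]
    if uniform.shape[0] != 2:
        raise DegeneracyError(
            f"uniform subspace has rank {uniform.shape[0]} (expected 2)"
        )
    uniform = np.array([_canonical_sign(v) for v in uniform])
    return PartialWarpBasis(be, lam, vecs, uniform, ref, tied)


def tps_grid(
    source: LandmarkConfiguration,
    target: LandmarkConfiguration,
    grid_density: int = 20,
    margin: float = 0.1,
) -> list[np.ndarray]:
    """Deformation grid of the TPS interpolant mapping source to target.

    Returns a list of polylines (m×2 arrays), one per grid line, after
    mapping a rectilinear grid over the source through the interpolant.  The
    interpolant reproduces the target exactly at every landmark.
    """
    if source.labels != target.labels:
        raise DimensionError("source and target must share landmark labels")
    pts = source.coords
    k = pts.shape[0]
    r = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if np.min(r + np.eye(k)) < 1e-12:
        raise DegeneracyError("coincident source landmarks")
    K = _tps_kernel(r)
    Q = np.column_stack([np.ones(k), pts])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target.coords
    try:
        coef = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError:
        raise DegeneracyError("singular TPS system") from None
    w, a = coef[:k], coef[k:]

    def warp(p: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(p[:, None, :] - pts[None, :, :], axis=-1)
        return np.column_stack([np.ones(len(p)), p]) @ a + _tps_kernel(d) @ w

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pad = margin * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_density)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_density)
    dense = 10 * grid_density
    lines = []
    for xv in xs:
        line = np.column_stack([np.full(dense, xv), np.linspace(ys[0], ys[-1], dense)])
        lines.append(warp(line))
    for yv in ys:
        line = np.column_stack([np.linspace(xs[0], xs[-1], dense), np.full(dense, yv)])
        lines.append(warp(line))
    return lines
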