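"""Procrustes/Boas superposition via the explicit J-matrix formalism.

The central object is the 4×2k matrix J built from a standardized mean form
mu = (x1, y1, ..., xk, yk) with sum(x) = sum(y) = sum(xy) = 0 and
sum(x² + y²) = 1:

    row 1:  (1/√k, 0, 1/√k, 0, ...)        horizontal centering
    row 2:  (0, 1/√k, 0, 1/√k, ...)        vertical centering
    row 3:  (-y1, x1, -y2, x2, ...)        rigid rotation of the plane
    row 4:  (x1, y1, x2, y2, ...)          centroid-size standardization

The rows are orthonormal, so subtracting sum_i J_i^t (J_i C) from a
coordinate vector C projects out position, orientation and scale in one
linear step.  For small variation around the mean this projection agrees
with the iterative Generalized Procrustes superposition to second order.
Boas coordinates omit the scale row (and the scaling step of the iterative
fit), preserving size information in the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ConvergenceError, DegeneracyError, DimensionError
from .io_landmarks import LandmarkConfiguration, LandmarkSample

__all__ = [
    "MeanFormWithJ",
    "ProcrustesFit",
    "BoasAllometry",
    "standardize_mean",
    "mean_form_in_place",
    "build_j",
    "build_j_3d",
    "project_to_shape_space",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "boas_allometry",
    "distance_gradient",
]

_DEGENERACY_TOL = 1e-12


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid Size: root of the summed squared distances to the centroid.

    The root convention keeps the measure linear under isotropic rescaling
    and gives the standardized mean form (sum of x²+y² equal to 1) Centroid
    Size exactly 1.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs < _DEGENERACY_TOL:
        raise DegeneracyError("all landmarks coincident: Centroid Size is zero")
    return cs


@dataclass
class MeanFormWithJ:
    """A standardized 2D mean form and its 4×2k nuisance-space basis J."""

    mu: np.ndarray
    J: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.mu.size // 2

    def configuration(self, specimen_id: str = "mean") -> LandmarkConfiguration:
        labels = self.labels or [f"L{i+1}" for i in range(self.k)]
        return LandmarkConfiguration.from_vector(self.mu, labels, 2, specimen_id)

    @property
    def coords(self) -> np.ndarray:
        return self.mu.reshape(-1, 2)


def build_j(mu: np.ndarray) -> np.ndarray:
    """Assemble the 4×2k matrix J from a standardized mean vector."""
    mu = np.asarray(mu, float)
    k = mu.size // 2
    x, y = mu[0::2], mu[1::2]
    J = np.zeros((4, 2 * k))
    J[0, 0::2] = 1.0 / np.sqrt(k)
    J[1, 1::2] = 1.0 / np.sqrt(k)
    J[2, 0::2], J[2, 1::2] = -y, x
    J[3, 0::2], J[3, 1::2] = x, y
    return J


def standardize_mean(config: LandmarkConfiguration) -> MeanFormWithJ:
    """Center, scale to unit Centroid Size, and rotate to principal axes.

    The returned form satisfies sum(x) = sum(y) = sum(xy) = 0 and
    sum(x²+y²) = 1.  The rotation's sign ambiguity (rotation by pi) is
    resolved by requiring the first landmark's x-coordinate nonnegative,
    ties broken by the second landmark, so the frame is reproducible.
    """
    if config.dim != 2:
        raise DimensionError("standardize_mean is 2D; use build_j_3d for 3D projection")
    if config.k < 3:
        raise DegeneracyError("k >= 3 landmarks required")
    coords = config.coords - config.coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(coords**2)))
    if cs < _DEGENERACY_TOL:
        raise DegeneracyError("coincident landmarks")
    coords = coords / cs
    # principal axes: diagonalize the 2x2 moment matrix, major axis -> x
    m = coords.T @ coords
    evals, evecs = np.linalg.eigh(m)  # ascending
    if evals[0] < 1e-12:
        raise DegeneracyError("collinear landmarks: degenerate principal axes")
    if (evals[1] - evals[0]) > 1e-9 * evals[1]:
        rot = evecs[:, ::-1]  # columns: major, minor
        if np.linalg.det(rot) < 0:
            rot[:, 1] = -rot[:, 1]
        coords = coords @ rot
    # tied moments (fourfold-symmetric forms like square grids): every frame
    # is a principal frame, so keep the input orientation — rotating would
    # make standardization non-idempotent
    # sign: rotation by pi
    for j in range(config.k):
        if abs(coords[j, 0]) > 1e-9:
            if coords[j, 0] < 0:
                coords = -coords
            break
    mu = coords.reshape(-1)
    return MeanFormWithJ(mu, build_j(mu), list(config.labels))


def mean_form_in_place(config: LandmarkConfiguration) -> MeanFormWithJ:
    """Center and scale to unit Centroid Size, keeping the input orientation.

    The rows of J are orthonormal for any centered unit-size form — the
    principal-axes rotation of :func:`standardize_mean` only fixes a
    reporting frame.  This variant serves per-contrast registrations, where
    the frame must stay comparable to the surrounding analysis rather than
    jump to each pair's own canonical axes.
    """
    if config.dim != 2:
        raise DimensionError("mean_form_in_place is 2D")
    coords = config.coords - config.coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(coords**2)))
    if cs < _DEGENERACY_TOL:
        raise DegeneracyError("coincident landmarks")
    mu = (coords / cs).reshape(-1)
    return MeanFormWithJ(mu, build_j(mu), list(config.labels))


def project_to_shape_space(C: np.ndarray, ref: MeanFormWithJ) -> np.ndarray:
    """Project out the four nuisance dimensions: C - sum_i J_i^t (J_i C)."""
    C = np.asarray(C, float)
    if C.shape[-1] != ref.J.shape[1]:
        raise DimensionError(
            f"vector length {C.shape[-1]} does not match 2k = {ref.J.shape[1]}"
        )
    return C - (C @ ref.J.T) @ ref.J


def build_j_3d(config: LandmarkConfiguration) -> tuple[np.ndarray, np.ndarray]:
    """3D analogue: centered unit-size mean plus a 7×3k orthonormal basis
    (3 translations, 3 infinitesimal rotations, 1 scale).

    No canonical principal-axes frame is imposed in 3D; the basis serves
    only for projection.
    """
    if config.dim != 3:
        raise DimensionError("build_j_3d requires a 3D configuration")
    coords = config.coords - config.coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(coords**2)))
    if cs < _DEGENERACY_TOL:
        raise DegeneracyError("coincident landmarks")
    coords = coords / cs
    k = config.k
    mu = coords.reshape(-1)
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    rows = np.zeros((7, 3 * k))
    for a in range(3):
        rows[a, a::3] = 1.0
    # infinitesimal rotations about z, x, y
    rows[3, 0::3], rows[3, 1::3] = -y, x
    rows[4, 1::3], rows[4, 2::3] = -z, y
    rows[5, 2::3], rows[5, 0::3] = -x, z
    rows[6] = mu
    q, r = np.linalg.qr(rows.T)
    if np.min(np.abs(np.diag(r))) < 1e-10:
        raise DegeneracyError("degenerate 3D configuration: nuisance basis rank-deficient")
    return mu, q.T


# ---------------------------------------------------------------------------
# Ordinary Procrustes alignment helpers (2D, rotation det = +1 only)
# ---------------------------------------------------------------------------

def _opa_rotation(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||X R - M||_F for centered k×2 arrays."""
    u, _, vt = np.linalg.svd(X.T @ M)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _align(X: np.ndarray, M: np.ndarray, scale: bool) -> tuple[np.ndarray, float, float]:
    """Center X and rotate (and optionally scale) onto M. Returns
    (aligned k×2, scale factor applied, rotation angle)."""
    Xc = X - X.mean(axis=0)
    R = _opa_rotation(Xc, M)
    XR = Xc @ R
    s = float(np.sum(XR * M) / np.sum(Xc**2)) if scale else 1.0
    theta = float(np.arctan2(R[0, 1], R[0, 0]))
    return s * XR, s, theta


@dataclass
class ProcrustesFit:
    """Result of an iterative (Generalized) Procrustes or Boas superposition.

    ``shape_coords`` holds J-projected deviations from the reference mean:
    orthogonal to all four rows of J for a scaled fit, to rows 1-3 only for
    a Boas fit (the scale direction is retained).  ``aligned`` holds the
    superposed configurations themselves (mean frame, 2k-vectors).
    """

    shape_coords: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    rotations: np.ndarray
    reference: MeanFormWithJ
    scaled: bool
    mean_vector: np.ndarray
    n_iterations: int

    @property
    def n(self) -> int:
        return self.shape_coords.shape[0]

    def sample(self) -> LandmarkSample:
        """Aligned configurations as a LandmarkSample."""
        labels = self.reference.labels
        return LandmarkSample.from_matrix(self.aligned, labels, 2)


def gpa(
    sample: LandmarkSample,
    scale: bool = True,
    recenter_tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesFit:
    """Generalized Procrustes superposition (Boas variant when scale=False).

    Each configuration is centered, scaled to unit Centroid Size when
    ``scale`` is true, and rotated (rotations only, no reflections) to the
    running mean; the mean is re-standardized each round and iteration stops
    when it moves by less than ``recenter_tol`` in Procrustes distance.
    """
    if sample.dim != 2:
        raise DimensionError("gpa currently supports 2D samples")
    if sample.n < 2:
        raise ValueError("gpa requires n >= 2 configurations")
    k = sample.k
    raw = [c.coords - c.coords.mean(axis=0) for c in sample]
    sizes = np.array([float(np.sqrt(np.sum(c**2))) for c in raw])
    if np.any(sizes < _DEGENERACY_TOL):
        raise DegeneracyError("degenerate configuration in sample")
    work = [c / s for c, s in zip(raw, sizes)] if scale else raw

    ref = standardize_mean(sample.configurations[0])
    mean = ref.mu.reshape(-1, 2)
    thetas = np.zeros(sample.n)
    aligned = list(work)
    it = 0
    for it in range(1, max_iter + 1):
        aligned = []
        for i, X in enumerate(work):
            R = _opa_rotation(X, mean)
            thetas[i] = float(np.arctan2(R[0, 1], R[0, 0]))
            aligned.append(X @ R)
        new_mean_cfg = LandmarkConfiguration(
            np.mean(aligned, axis=0), sample.labels, "mean"
        )
        new_ref = standardize_mean(new_mean_cfg)
        shift = float(np.linalg.norm(new_ref.mu - ref.mu))
        # express the running mean in the canonical frame of the new reference
        mean_avg = np.mean(aligned, axis=0)
        mean_avg -= mean_avg.mean(axis=0)
        Rc = _opa_rotation(mean_avg, new_ref.mu.reshape(-1, 2))
        mean = mean_avg @ Rc
        ref = new_ref
        if shift < recenter_tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last shift {shift:.3e})"
        )
    # final pass: rotate everything into the canonical frame of ref
    target = ref.mu.reshape(-1, 2) if scale else mean
    aligned_vecs = np.empty((sample.n, 2 * k))
    for i, X in enumerate(work):
        R = _opa_rotation(X, target)
        thetas[i] = float(np.arctan2(R[0, 1], R[0, 0]))
        aligned_vecs[i] = (X @ R).reshape(-1)
    mean_vec = aligned_vecs.mean(axis=0)
    dev = aligned_vecs - mean_vec
    P = ref.J if scale else ref.J[:3]
    shape_coords = dev - (dev @ P.T) @ P
    return ProcrustesFit(
        shape_coords=shape_coords,
        aligned=aligned_vecs,
        centroid_sizes=sizes,
        rotations=thetas,
        reference=ref,
        scaled=scale,
        mean_vector=mean_vec,
        n_iterations=it,
    )


def procrustes_distance(
    a: LandmarkConfiguration,
    b: LandmarkConfiguration,
    mode: Literal["local", "reference"] = "local",
    ref: MeanFormWithJ | None = None,
) -> float:
    """Procrustes distance between two configurations.

    mode='local': both forms are registered through the J of their own
    pairwise mean (a fresh registration per pair, as recommended for
    contrasts), which approximates the full similarity-transform minimum to
    high relative accuracy for forms within moderate shape distance.

    mode='reference': both forms are registered through the supplied
    reference's J — the 'grand mean' registration whose bias the local mode
    corrects.
    """
    if a.labels != b.labels or a.dim != b.dim:
        raise DimensionError("configurations must share landmark labels and dimension")
    if mode == "reference":
        if ref is None:
            raise ValueError("mode='reference' requires a reference MeanFormWithJ")
        va = _align(a.coords, ref.coords, scale=True)[0].reshape(-1)
        vb = _align(b.coords, ref.coords, scale=True)[0].reshape(-1)
        return float(np.linalg.norm(project_to_shape_space(va - vb, ref)))
    if mode != "local":
        raise ValueError(f"unknown mode {mode!r}")
    # symmetric two-form superposition: canonicalize each, then alternate
    # alignment to the running pairwise mean
    fa = standardize_mean(a).coords
    fb = standardize_mean(b).coords
    ref2 = None
    for _ in range(60):
        avg = LandmarkConfiguration((fa + fb) / 2.0, a.labels, "pairmean")
        new_ref = standardize_mean(avg)
        fa_new = _align(fa, new_ref.coords, scale=True)[0]
        fb_new = _align(fb, new_ref.coords, scale=True)[0]
        delta = max(
            float(np.max(np.abs(fa_new - fa))), float(np.max(np.abs(fb_new - fb)))
        )
        fa, fb, ref2 = fa_new, fb_new, new_ref
        if delta < 1e-15:
            break
    d = (fa - fb).reshape(-1)
    return float(np.linalg.norm(project_to_shape_space(d, ref2)))


@dataclass
class BoasAllometry:
    """Per-landmark allometric regression against a size variable.

    ``slopes`` are the 2-vectors of simple-regression slopes of each
    landmark's Boas coordinates on the size variable; ``radial`` are unit
    vectors from the centroid to the landmark's mean position.  A fit is
    well registered when slopes point radially (misalignment near zero) and
    scale with the landmark's distance from the centroid.
    """

    labels: list[str]
    slopes: np.ndarray
    radial: np.ndarray
    mean_positions: np.ndarray
    misalignment: np.ndarray  # radians, in [0, pi]


def boas_allometry(fit: ProcrustesFit, size_var: np.ndarray) -> BoasAllometry:
    """Regress Boas coordinates on a size variable, landmark by landmark."""
    if fit.scaled:
        raise ValueError("boas_allometry requires a Boas fit (gpa with scale=False)")
    size_var = np.asarray(size_var, float)
    if size_var.shape != (fit.n,):
        raise DimensionError("size_var length must equal the number of specimens")
    s = size_var - size_var.mean()
    ss = float(s @ s)
    if ss < 1e-30:
        raise ValueError("size variable has zero variance")
    dev = fit.aligned - fit.aligned.mean(axis=0)
    slopes = (s @ dev / ss).reshape(-1, 2)
    mean_pos = fit.mean_vector.reshape(-1, 2)
    centroid = mean_pos.mean(axis=0)
    radial_raw = mean_pos - centroid
    norms = np.linalg.norm(radial_raw, axis=1)
    radial = radial_raw / np.where(norms > 0, norms, 1.0)[:, None]
    slope_norm = np.linalg.norm(slopes, axis=1)
    cosang = np.einsum("ij,ij->i", slopes, radial) / np.where(
        slope_norm > 0, slope_norm, 1.0
    )
    mis = np.arccos(np.clip(cosang, -1.0, 1.0))
    labels = fit.reference.labels or [f"L{i+1}" for i in range(fit.reference.k)]
    return BoasAllometry(labels, slopes, radial, mean_pos, mis)


def distance_gradient(ref: MeanFormWithJ, pair: Sequence[str]) -> np.ndarray:
    """Shape-space direction along which an interlandmark distance grows.

    The raw gradient of the distance between two named landmarks is a pair
    of equal and opposite unit vectors at those landmarks, pointing apart.
    Its components along all four rows of J are removed (the scale row is
    the essential one; the first three are annihilated anyway for a
    centered, torque-free gradient) and the result is normalized.
    """
    la, lb = pair
    if la == lb:
        raise ValueError("distance_gradient requires two distinct landmark labels")
    labels = ref.labels or [f"L{i+1}" for i in range(ref.k)]
    try:
        ia, ib = labels.index(la), labels.index(lb)
    except ValueError as e:
        raise ValueError(f"unknown landmark label: {e}") from None
    pa, pb = ref.coords[ia], ref.coords[ib]
    d = float(np.linalg.norm(pa - pb))
    if d < _DEGENERACY_TOL:
        raise DegeneracyError("coincident landmarks: distance gradient undefined")
    g = np.zeros(2 * ref.k)
    g[2 * ia : 2 * ia + 2] = (pa - pb) / d
    g[2 * ib : 2 * ib + 2] = (pb - pa) / d
    v = project_to_shape_space(g, ref)
    nv = float(np.linalg.norm(v))
    if nv < _DEGENERACY_TOL:
        raise DegeneracyError("distance gradient lies entirely in the nuisance space")
    return v / nv
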