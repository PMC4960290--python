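"""Synthetic data generators.

Everything the rest of the toolkit needs for testing and demonstration is
generated here: rectangular landmark grids, offset isotropic Mardia-Dryden
samples N(mu, sigma² I_2k), the four classic single-pattern displacement
fields (uniform/affine, growth gradient, Pinocchio, random direction) at a
stated Procrustes length, Brownian shape evolution along a dated phylogeny,
and correlation matrices with an exact one-general/several-special factor
structure.

Random-number contract: every stochastic generator takes an explicit seed
(or Generator) and creates its own ``numpy.random.Generator``; there is no
global state, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DimensionError
from .io_landmarks import LandmarkConfiguration, LandmarkSample, SquareMatrixInput
from .procrustes import MeanFormWithJ, project_to_shape_space

__all__ = [
    "IsotropicModel",
    "PatternField",
    "grid_config",
    "sample_isotropic",
    "pattern_field",
    "brownian_tree_shapes",
    "random_phylogeny",
    "factor_correlation_matrix",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def grid_config(rows: int, cols: int, spacing: float = 1.0) -> LandmarkConfiguration:
    """Rectangular lattice of rows × cols landmarks, row-major labels.

    The 7×7 grid (49 landmarks, hence 46 partial warps after removing the
    three affine null dimensions) is the standard testbed for the deflated
    reference distribution.
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid_config requires rows, cols >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xs, ys = np.meshgrid(np.arange(cols) * spacing, np.arange(rows) * spacing)
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    labels = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    return LandmarkConfiguration(coords, labels, f"grid{rows}x{cols}")


@dataclass
class IsotropicModel:
    """The offset isotropic Mardia-Dryden model N(mu, sigma² I_2k):
    independent circular Gaussian noise of common scale at every landmark
    of a mean form."""

    mu: np.ndarray
    sigma: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_reference(cls, ref: MeanFormWithJ, sigma: float) -> "IsotropicModel":
        return cls(ref.mu.copy(), sigma, list(ref.labels) or None)


def sample_isotropic(
    model: IsotropicModel, n: int, seed: int | np.random.Generator | None = None
) -> LandmarkSample:
    """Draw n iid configurations from N(mu, sigma² I_2k)."""
    if n < 1:
        raise ValueError("n >= 1 required")
    rng = _rng(seed)
    mat = model.mu[None, :] + model.sigma * rng.standard_normal((n, model.mu.size))
    k = model.mu.size // 2
    labels = model.labels or [f"L{i+1}" for i in range(k)]
    return LandmarkSample.from_matrix(mat, labels, 2)


@dataclass
class PatternField:
    """One of the four classic displacement-field vocabularies, all
    normalized to the same Procrustes length after J-projection so that no
    summary statistic built on that length can tell them apart.

    kind='uniform'   affine (zero bending energy) field; ``direction`` mixes
                     the two uniform basis fields (shear vs dilation ratio),
                     as an angle in radians.
    kind='gradient'  displacement (a + b·s)·u with s the position along the
                     unit axis u at ``direction`` radians; a growth gradient.
    kind='pinocchio' a single landmark (``landmark`` label or index) pushed
                     along ``direction``; everything else fixed pre-projection.
    kind='random'    iid circular Gaussian little vectors at every landmark
                     (seeded); a meaningless composite direction.
    """

    kind: Literal["uniform", "gradient", "pinocchio", "random"]
    amplitude: float = 0.1
    direction: float = 0.0
    landmark: int | str | None = None
    gradient_offset: float = 0.0
    gradient_slope: float = 1.0


def pattern_field(
    ref: MeanFormWithJ,
    spec: PatternField,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Build the requested 2k displacement field, project it to shape space,
    and rescale to the requested Procrustes length."""
    k = ref.k
    pts = ref.coords
    raw = np.zeros(2 * k)
    if spec.kind == "uniform":
        # two independent affine shape fields: pure shear and aspect dilation
        x, y = pts[:, 0], pts[:, 1]
        shear = np.zeros(2 * k)
        shear[0::2] = y
        shear[1::2] = x
        dilat = np.zeros(2 * k)
        dilat[0::2] = x
        dilat[1::2] = -y
        raw = np.cos(spec.direction) * shear + np.sin(spec.direction) * dilat
    elif spec.kind == "gradient":
        u = np.array([np.cos(spec.direction), np.sin(spec.direction)])
        s = pts @ u
        mag = spec.gradient_offset + spec.gradient_slope * s
        raw[0::2] = mag * u[0]
        raw[1::2] = mag * u[1]
    elif spec.kind == "pinocchio":
        if spec.landmark is None:
            raise ValueError("pinocchio pattern requires a landmark")
        if isinstance(spec.landmark, str):
            labels = ref.labels or [f"L{i+1}" for i in range(k)]
            idx = labels.index(spec.landmark)
        else:
            idx = int(spec.landmark)
        raw[2 * idx] = np.cos(spec.direction)
        raw[2 * idx + 1] = np.sin(spec.direction)
    elif spec.kind == "random":
        raw = _rng(seed).standard_normal(2 * k)
    else:
        raise ValueError(f"unknown pattern kind {spec.kind!r}")
    v = project_to_shape_space(raw, ref)
    norm = float(np.linalg.norm(v))
    if norm < 1e-14:
        raise ValueError("pattern field vanishes after projection")
    return spec.amplitude * v / norm


def brownian_tree_shapes(
    tree,
    root: LandmarkConfiguration,
    rate_matrix: np.ndarray | float,
    seed: int | np.random.Generator | None = None,
) -> LandmarkSample:
    """Brownian motion of a landmark configuration along a dated phylogeny.

    Each branch of length t adds a Gaussian increment with covariance
    t · rate over the 2k coordinates, accumulated from root to tips.  A
    scalar rate means isotropic Brownian motion (rate · I_2k).  Tips are
    returned as a LandmarkSample whose specimen ids are the tip names, in
    the tree's tip order.
    """
    rng = _rng(seed)
    p = root.k * root.dim
    if np.isscalar(rate_matrix):
        chol = float(np.sqrt(rate_matrix)) * np.eye(p) if rate_matrix > 0 else np.zeros((p, p))
    else:
        rate = np.asarray(rate_matrix, float)
        if rate.shape == (p,):
            chol = np.diag(np.sqrt(rate))
        elif rate.shape == (p, p):
            chol = np.linalg.cholesky(rate + 1e-15 * np.eye(p))
        else:
            raise DimensionError(
                f"rate matrix must be scalar, length-{p} diagonal, or {p}×{p}"
            )
    root_vec = root.as_vector()
    values: dict[int, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}

    def walk(node_id: int, value: np.ndarray) -> None:
        values[node_id] = value
        for child, blen in tree.children(node_id):
            incr = chol @ rng.standard_normal(p) * np.sqrt(blen)
            walk(child, value + incr)

    walk(tree.root, root_vec)
    for tip_id, name in tree.tip_names.items():
        tips[name] = values[tip_id]
    mat = np.stack([tips[name] for name in tree.tip_order])
    return LandmarkSample.from_matrix(mat, root.labels, root.dim, list(tree.tip_order))


def random_phylogeny(
    n_tips: int,
    seed: int | np.random.Generator | None = None,
    mean_branch: float = 1.0,
):
    """Random rooted bifurcating tree with positive branch lengths.

    Topology by random sequential joins; branch lengths iid uniform on
    (0.5, 1.5) · mean_branch.  Tip names are t1..tn.
    """
    from .phylo_contrasts import Phylogeny

    if n_tips < 2:
        raise ValueError("n_tips >= 2 required")
    rng = _rng(seed)

    def blen() -> float:
        return float(mean_branch * rng.uniform(0.5, 1.5))

    subtrees = [f"t{i+1}:{blen():.10g}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        if len(subtrees) == 0:
            subtrees.append(f"({a},{b})")
        else:
            subtrees.append(f"({a},{b}):{blen():.10g}")
    return Phylogeny.from_newick_string(subtrees[0] + ";")


def factor_correlation_matrix(
    g: Sequence[float],
    specials: Sequence[float],
    blocks: Sequence[Sequence[int]],
    variable_names: Sequence[str] | None = None,
) -> SquareMatrixInput:
    """Correlation matrix with exact structure g⊗g + sum_i s_i⊗s_i off the
    diagonal and ones on it.

    ``specials[i]`` is the loading shared by every variable in ``blocks[i]``
    (0-based indices); variables outside all blocks carry no special factor.
    """
    g = np.asarray(g, float)
    p = g.size
    R = np.outer(g, g)
    for loading, block in zip(specials, blocks):
        s = np.zeros(p)
        s[list(block)] = float(loading)
        R += np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    off = R[~np.eye(p, dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise ValueError("factor structure implies off-diagonal correlation >= 1")
    names = list(variable_names) if variable_names else [f"v{i+1}" for i in range(p)]
    return SquareMatrixInput(R, names, "correlation")
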