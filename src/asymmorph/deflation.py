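"""The deflated (self-similar) Procrustes reference distribution and the
BE-PWV integration statistic.

Deflation turns an isotropic Mardia-Dryden distribution into a scale-free
null: drop the uniform (affine) component and give each partial warp a score
variance inversely proportional to its bending-energy eigenvalue (2D; the
squared eigenvalue in 3D).  This is exactly a relative eigenanalysis of the
isotropic model against the bending-energy quadratic form.  Under the
resulting distribution the nonuniform shape variation of every sub-square of
a grid — any size, position or orientation — follows one and the same
distribution, so no local feature of an individual specimen's deformation
grid is interpretable on its own.

The diagnostic is the BE-PWV plot: log partial-warp variance against log
partial-warp bending energy.  Slope -1 marks self-similarity; variance
falling *faster* than 1/BE (slope below -1) is the signature of integration;
a flat plot (slope 0) is the isotropic, fully disintegrated case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegeneracyError
from .io_landmarks import LandmarkSample
from .procrustes import MeanFormWithJ, _align
from .tps_warps import PartialWarpBasis, partial_warp_basis

__all__ = [
    "BEPWVTable",
    "sample_deflated",
    "be_pwv_table",
    "integration_test",
    "IntegrationVerdict",
    "fit_scaling_regimes",
    "ScalingRegimes",
]


@dataclass
class BEPWVTable:
    """Per-warp (bending energy, variance) pairs and their log-log fit.

    ``pw_variance`` sums the d Cartesian score variances of each warp, so a
    7×7 grid yields one 46-point plot.  The uniform component has bending
    energy zero and cannot sit on a log-log plot; its variance is held
    separately and excluded from the regression.
    """

    warp_index: np.ndarray
    bending_energy: np.ndarray
    pw_variance: np.ndarray
    slope: float
    intercept: float
    uniform_variance: float
    n_specimens: int
    scores: np.ndarray | None = None  # n × (2·n_warps) per-specimen warp scores

    @property
    def log_be(self) -> np.ndarray:
        return np.log(self.bending_energy)

    @property
    def log_pwv(self) -> np.ndarray:
        return np.log(self.pw_variance)


def sample_deflated(
    ref: MeanFormWithJ,
    n: int,
    sigma: float,
    seed: int | np.random.Generator | None = None,
    basis: PartialWarpBasis | None = None,
) -> LandmarkSample:
    """Draw n configurations from the deflated distribution around a mean.

    Each partial warp j receives an independent N(0, sigma²/lambda_j) score
    on each Cartesian axis; the uniform component is omitted entirely.
    Configurations are mu plus the summed score-weighted warp directions.
    Identical seeds give bit-identical samples.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if basis is None:
        basis = partial_warp_basis(ref)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = basis.eigenvalues
    sd = sigma / np.sqrt(lam)  # per-axis score sd, variance sigma²/lambda
    scores = rng.standard_normal((n, lam.size, 2)) * sd[None, :, None]
    dirs = basis.shape_directions()  # rows: (warp0,x),(warp0,y),(warp1,x),...
    flat = scores.reshape(n, -1)  # matches dirs row order
    mat = ref.mu[None, :] + flat @ dirs
    labels = ref.labels or [f"L{i+1}" for i in range(ref.k)]
    return LandmarkSample.from_matrix(mat, labels, 2)


def be_pwv_table(
    sample: LandmarkSample,
    ref: MeanFormWithJ,
    basis: PartialWarpBasis | None = None,
    align: bool = True,
) -> BEPWVTable:
    """Partial-warp variances of a sample and the log-log slope against BE.

    Each configuration is registered onto the reference (centered, scaled to
    unit Centroid Size, rotated) unless ``align=False``, then scored on the
    warp directions; per-warp variance sums the d Cartesian components.  The
    headline slope is the plain OLS fit of log variance on log bending
    energy — the paper-trail quantity every integration claim rests on.
    """
    if sample.n < 3:
        raise ValueError("variance requires n >= 3 specimens")
    if basis is None:
        basis = partial_warp_basis(ref)
    X = np.empty((sample.n, 2 * ref.k))
    for i, c in enumerate(sample):
        if align:
            X[i] = _align(c.coords, ref.coords, scale=True)[0].reshape(-1)
        else:
            X[i] = c.as_vector()
    dev = X - X.mean(axis=0)
    dirs = basis.shape_directions()
    scores = dev @ dirs.T  # n × (2·n_warps)
    var_xy = scores.var(axis=0, ddof=1)
    pwv = var_xy[0::2] + var_xy[1::2]
    uni_scores = dev @ basis.uniform_basis.T
    uniform_variance = float(np.sum(uni_scores.var(axis=0, ddof=1)))
    lam = basis.eigenvalues
    floor = 1e-12 * float(pwv.max()) if pwv.max() > 0 else 0.0
    ok = pwv > floor
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} partial-warp variances underflow: "
            "slope computed on the remaining warps"
        )
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(np.log(lam[ok]), np.log(pwv[ok]), 1)
    else:
        slope, intercept = np.nan, np.nan
        warnings.warn("fewer than 2 usable warps: BE-PWV slope undefined")
    return BEPWVTable(
        warp_index=np.arange(1, lam.size + 1),
        bending_energy=lam.copy(),
        pw_variance=pwv,
        slope=float(slope),
        intercept=float(intercept),
        uniform_variance=uniform_variance,
        n_specimens=sample.n,
        scores=scores,
    )


@dataclass
class IntegrationVerdict:
    """Bootstrap assessment of a BE-PWV slope against the self-similar -1."""

    slope: float
    ci_low: float
    ci_high: float
    verdict: Literal["integrated", "disintegrated", "self-similar/indeterminate"]
    n_boot: int


def integration_test(
    table: BEPWVTable,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> IntegrationVerdict:
    """Bootstrap the BE-PWV slope over specimens and compare with -1.

    'integrated' when the whole confidence interval lies below -1 (variance
    of features falls faster than the inverse of their bending energy);
    'disintegrated' when it lies wholly above; otherwise the data are
    compatible with the self-similar reference.  The bootstrap resamples
    specimens and recomputes every per-warp variance, so the table must
    carry per-specimen scores (the default from :func:`be_pwv_table`).
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable confidence bounds")
    if table.bending_energy.size < 4:
        raise DegeneracyError("integration test requires >= 4 partial warps")
    if table.scores is None:
        raise ValueError("table lacks per-specimen scores; rebuild with be_pwv_table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = table.scores
    log_be = table.log_be

    def slope_of(s: np.ndarray) -> float:
        v = s.var(axis=0, ddof=1)
        pwv = v[0::2] + v[1::2]
        return float(np.polyfit(log_be, np.log(pwv), 1)[0])

    point = slope_of(scores)
    boots = np.empty(n_boot)
    n = scores.shape[0]
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = slope_of(scores[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    if hi < -1.0:
        verdict = "integrated"
    elif lo > -1.0:
        verdict = "disintegrated"
    else:
        verdict = "self-similar/indeterminate"
    return IntegrationVerdict(point, float(lo), float(hi), verdict, n_boot)


@dataclass
class ScalingRegimes:
    """Piecewise log-log scaling structure of a BE-PWV table."""

    n_regimes: int
    breakpoints: list[float]  # log-BE positions between segments
    slopes: list[float]
    intercepts: list[float]
    segments: list[np.ndarray]  # warp indices (1-based) per segment
    bic: float


def fit_scaling_regimes(table: BEPWVTable, max_regimes: int = 2) -> ScalingRegimes:
    """Segment the BE-PWV plot into 1..max_regimes log-log scaling regimes.

    Candidate breakpoints lie between consecutive warps on the sorted log-BE
    axis; each segment gets its own OLS line and the segmentation is chosen
    by BIC.  A mosquito-wing-style mixed regime (flat at one end of the
    scale, self-similar at the other) shows up as two segments with a knee.
    """
    n = table.bending_energy.size
    if n < 6:
        raise ValueError("regime fitting requires >= 6 warps")
    if not (1 <= max_regimes <= 3):
        raise ValueError("max_regimes must be in 1..3")
    if max_regimes > n // 3:
        raise ValueError(f"max_regimes={max_regimes} exceeds rows/3 = {n // 3}")
    order = np.argsort(table.bending_energy)
    x = np.log(table.bending_energy[order])
    y = np.log(table.pw_variance[order])
    if np.ptp(x) < 1e-12:
        raise DegeneracyError("degenerate abscissa: all bending energies equal")
    widx = table.warp_index[order]
    min_seg = 3

    def seg_fit(i: int, j: int) -> tuple[float, float, float]:
        sl, ic = np.polyfit(x[i:j], y[i:j], 1)
        rss = float(np.sum((y[i:j] - (sl * x[i:j] + ic)) ** 2))
        return sl, ic, rss

    best: ScalingRegimes | None = None
    for m in range(1, max_regimes + 1):
        cuts_iter = _cut_combinations(n, m, min_seg)
        for cuts in cuts_iter:
            bounds = [0, *cuts, n]
            fits = [seg_fit(bounds[i], bounds[i + 1]) for i in range(m)]
            rss = sum(f[2] for f in fits)
            n_par = 2 * m + (m - 1)
            bic = n * np.log(max(rss, 1e-300) / n) + n_par * np.log(n)
            if best is None or bic < best.bic:
                best = ScalingRegimes(
                    n_regimes=m,
                    breakpoints=[float((x[c - 1] + x[c]) / 2.0) for c in cuts],
                    slopes=[f[0] for f in fits],
                    intercepts=[f[1] for f in fits],
                    segments=[
                        widx[bounds[i] : bounds[i + 1]].copy() for i in range(m)
                    ],
                    bic=float(bic),
                )
    assert best is not None
    return best


def _cut_combinations(n: int, m: int, min_seg: int):
    """All ways to place m-1 ordered cuts leaving segments of >= min_seg."""
    if m == 1:
        yield ()
        return
    import itertools

    positions = range(min_seg, n - min_seg + 1)
    for cuts in itertools.combinations(positions, m - 1):
        bounds = [0, *cuts, n]
        if all(bounds[i + 1] - bounds[i] >= min_seg for i in range(m)):
            yield cuts
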