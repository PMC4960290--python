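# Methods

This note documents the models implemented in `asymmorph`, the conventions
and defaults chosen where the literature leaves them open, what the
synthetic generators do and do not emulate, and known limitations.

## The J-matrix superposition

For k landmarks in 2D, the mean form is standardized to
`Σxᵢ = Σyᵢ = Σxᵢyᵢ = 0`, `Σ(xᵢ²+yᵢ²) = 1`: centered, unit Centroid Size,
principal axes horizontal/vertical.  The 4×2k matrix J (two centering rows,
one infinitesimal-rotation row `(−y₁,x₁,…)`, one scale row `(x₁,y₁,…)`) has
orthonormal rows, and `C − Σ Jᵢᵗ(JᵢC)` removes position, orientation and
scale in one linear step.  For small variation this projection agrees with
iterative Generalized Procrustes superposition to second order in the noise
amplitude, which the test suite asserts directly.

Conventions:

- **Centroid Size** is the *square root* of the summed squared distances to
  the centroid.  The root keeps CS linear under isotropic rescaling and
  makes the standardized mean's CS exactly 1; a sum-of-squares convention
  would rescale sizes but change no shape quantity.
- **Canonical frame.** The principal-axes rotation of `standardize_mean`
  resolves its 180° ambiguity by requiring the first landmark's
  x-coordinate nonnegative (ties broken by the second landmark).  When the
  two principal moments are numerically tied (fourfold-symmetric forms such
  as square grids) *no* rotation is applied: every frame is then a
  principal frame, and rotating by the arbitrary basis an eigensolver
  returns would make standardization non-idempotent.
- **Registrations that must stay comparable** (per-contrast recentering,
  sub-square extraction) use `mean_form_in_place`: centering and scaling
  only.  The orthonormality of J does not require `Σxy = 0`; the
  principal-axes step is purely a reporting convention, and
  re-canonicalizing every pairwise mean would express each contrast in its
  own arbitrary frame.
- **GPA** excludes reflections (rotations with det +1 only): biological
  forms are chirally meaningful.  Convergence: successive standardized
  means within 1e-10 (Euclidean, both in the canonical frame), at most 100
  iterations.  `ProcrustesFit.shape_coords` holds J-projected deviations
  from the mean (rows 1–3 only for Boas fits, which retain size);
  `ProcrustesFit.aligned` holds the superposed configurations.
- **Local (recentered) Procrustes distance** superposes the two forms on
  their own pairwise mean by a symmetric two-form iteration and measures
  the J-projected difference there.  On pairs within shape distance 0.2
  this matches a brute-force minimization of `‖A′ − sRB + t‖` to machine
  precision (asserted at 1e-3 relative tolerance).
- **Distance gradients**: the gradient of an interlandmark distance is the
  pair of opposed unit vectors at the two landmarks; all four rows of J are
  projected out (the scale row is the essential correction — the other
  three are annihilated anyway for centered, torque-free gradients, so the
  uniform contract costs nothing) and the result is normalized.
- **3D** is supported at the projection level only (7×3k basis: three
  translations, three orthonormalized infinitesimal rotations, scale); no
  canonical 3D reporting frame is imposed.

## Bending energy, partial warps, deflation

The bending-energy matrix is the upper-left k×k block of the inverse
bordered thin-plate-spline system with kernel `U(r) = r² log r` and affine
border `[1 | x | y]`.  Kernel normalization is a free constant: using
`r² log r²` would exactly double every eigenvalue, shifting log-BE by a
constant and leaving every BE–PWV slope unchanged; the choice is documented
so eigenvalues can be reconciled across implementations.  The matrix is PSD
with rank k−3 (affine fields are its null space), its eigenvectors are the
partial warps, ordered ascending (largest-scale first).  Exact eigenvalue
ties on symmetric configurations are resolved by a deterministic secondary
sort on sign-canonicalized eigenvector coordinates, so warp numbering is
reproducible.  The uniform (affine) shape subspace is the J-projection of
the four fields `x∂x, y∂x, x∂y, y∂y`, orthonormalized; shape space then
decomposes exactly as 2k = 4 (nuisance) + 2 (uniform) + 2(k−3) (warps),
which the suite asserts.

The deflated reference distribution draws each warp's score on each
Cartesian axis as `N(0, σ²/λⱼ)` (in 3D the rule squares the BE matrix, i.e.
`σ²/λⱼ²`; implemented, no printed value to test against) and omits the
uniform component entirely.  This is precisely the relative eigenanalysis
of the isotropic model against the bending-energy quadratic form — the test
suite verifies that the warp directions coincide with those relative
eigenvectors on a generic mean.  Consequences, both tested:

- the BE–PWV plot (natural logs; the slope is base-invariant) has slope −1;
  at n = 200 on the 7×7 grid a single realization lands within ±0.05 of −1
  for over 90% of seeds;
- the nonuniform shape distribution of every sub-square of a grid sample is
  the same, at any scale and position (asserted via the covariance distance
  between sub-square score covariances against a replicate-noise floor at
  n = 20,000).

Per-warp variance sums the d Cartesian score variances (one point per warp:
46 for the 7×7 grid).  The uniform term has bending energy zero and cannot
sit on the log–log plot; its variance is reported separately and excluded
from the regression — no fictitious scale is imputed for it.  The headline
slope is plain OLS; uncertainty comes from a specimen bootstrap
(default 1000 draws, 95% interval).  The integration verdict is
"integrated" only when the whole interval lies below −1, "disintegrated"
when wholly above.  `fit_scaling_regimes` fits 1–3 independent OLS segments
over candidate breakpoints on the sorted log-BE axis (≥3 warps per
segment), selected by BIC — the mixed-regime pattern seen in strongly
canalized structures appears as two segments with a knee.

Sigma defaults to 0.02 in the examples and acceptance runs: small enough
that the linear (tangent-space) treatment is exact to well below sampling
error on a unit-CS mean, and immaterial to the slope, which is scale-free.

## Relative eigenanalysis

`relative_eigen(A, B)` solves `A v = λ B v` by Cholesky-whitening B and
running a symmetric eigensolve — stabler than general-purpose generalized
solvers when B is ill-conditioned.  Eigenvectors are B-orthonormal with the
largest-magnitude coordinate positive.  The covariance distance
`√Σ log²λ` is symmetric, zero iff A = B, congruence-invariant, and additive
along single-factor inflations (a geodesic property the tests verify
numerically); the triangle inequality is not asserted.  A PSD A with null
rank yields distance +∞ with the rank reported — explicit is safer than
clamping a log at an arbitrary floor.

One caveat established during development: for two isotropic populations
whose means differ by Procrustes length ρ, covariances computed each in its
own registration and compared in a common basis are *identical* to first
order — the often-quoted 1±ρ distortion arises only when one and the same
population is registered through the J of a mean displaced by ρ and
compared against its correct registration, and even there the exact
extremes are cos²ρ and cos²ρ·cos²2ρ (bidirectionally ≈ 1±ρ only in the
realistic mid-range ρ ≈ 0.2).  The acceptance suite tests the
misregistration construction at its stated tolerance and the mid-range ρ
passes; the small- and large-shift cases document the second-order nature
of the effect.

## Wright general/special factors

The model fits only the off-diagonal of a correlation matrix:
`R_off ≈ g⊗g + Σ sᵢ⊗sᵢ`, with g ≥ 0 loading every variable and each
special factor constant on its block and zero elsewhere (unequal
within-block loadings are out of scope).  Estimation: coordinate descent on
the cross-block cells for g (each update is the exact one-dimensional
least-squares optimum, so the objective decreases monotonically; initialized
at the square roots of cross-block row means; tolerance 1e-10), then each
block's loading is the square root of its mean within-block residual,
clamped at zero with a warning when negative.  Wright's own estimation
procedure for the historical leghorn fit is not recorded; this fit
reproduces his printed loadings to ~0.001 on g and ~0.007 on the specials,
well inside the ±0.02 band used in the tests.  Factor scores are
`data·g/‖g‖²`, optionally rescaled to unit variance.

## Phylogenetic contrasts

`felsenstein_contrasts` is the classic pruning recursion (contrast =
daughter difference; duration = sum of daughter branch lengths after the
`v₁v₂/(v₁+v₂)` stem extension; ancestral value = branch-length-weighted
average), run vectorized over coordinates, and additionally returns the
tip-weight matrix so tests can verify against the explicit Brownian
covariance: normalized contrast weights satisfy `W V Wᵀ = I` and the root
value is the GLS mean, both to 1e-9.

`shape_contrasts` superposes the tip sample (scaled GPA), runs the
recursion on the aligned configurations, and normalizes each contrast by
√duration.  With `recenter=True`, each contrast's two endpoint forms — tips
or reconstructed ancestors — are re-registered through the J of their own
pairwise mean (orientation-preserving, see above) before differencing, and
that registration is stored.  The pairwise-mean rule at internal nodes is
this package's choice: the recentering argument is demonstrated for tip
pairs in the literature, and the same rule is the natural extension.
Polytomies are rejected rather than arbitrarily resolved, because the
resolution order changes the contrasts and no principled default exists.

Relative warps of contrasts are the SVD axes of the contrast matrix with no
further centering (contrasts have expectation zero under the Brownian
null); tip scores project the tips' grand-mean-frame shape coordinates on
those axes.  The winnowing scan removes the leading r axes (r = 0…max),
recomputes pairwise tip shape distances in the orthocomplement (grand-mean
frame — after removing axes a fresh per-pair registration is no longer well
defined), pairs them with patristic distances, and reports a lowess smooth
(span 2/3, 3 robustness iterations, configurable) plus the through-origin
regression of squared distance on divergence time with its R².  A
patristic-distance cap is available and off by default.

## Two-block statistics

RV uses the Escoufier normalization
`tr(S_XY S_YX)/√(tr(S_XX²)tr(S_YY²))` with n−1 covariance denominators
(RV itself is denominator-invariant; the PLS singular values are not, so
the convention is stated).  Its invariance under separate within-block
rotations is asserted in the tests as the property that disqualifies it as
a pattern descriptor.  `pls_svd` decomposes S_XY; the covariance of the
i-th score pair equals the i-th singular value and `Σσ²` equals the RV
numerator, which ties the two statistics together formally.  The distance
regression is the through-origin slope `Σd₁d₂/Σd₁²` over unordered pairs,
diagonals omitted; no permutation p-value is attached by default.

## Synthetic generators

Every generator takes an explicit seed and builds its own
`numpy.random.Generator`; identical seeds are bit-reproducible.  The
generators emulate: isotropic landmark noise around a mean form (the offset
Mardia–Dryden model), deflated self-similar variation on grids, the four
classic single-pattern fields normalized to a common Procrustes length
(growth gradient parameterized as displacement `(a + b·s)·u` along an axis
u — the simplest field matching the verbal description), isotropic or
anisotropic Brownian motion of shape along a dated tree (random topologies
by sequential joins, branch lengths uniform on 0.5–1.5 of the mean), and
exact factor-structured correlation matrices.

What they do *not* emulate — and hence what passing tests cannot show about
real data: digitizing error that varies by landmark, semilandmark sliding,
allometric curvature, measurement covariance between repeated specimens,
non-Brownian (selective) evolutionary regimes, and 3D articulated
structures.  The generators define study conditions for verifying the
machinery, not a claim that real data behave this way.

## Problem sizes and numerical choices

Default test and acceptance scales: deflated-slope calibration at n = 200
over 40 seeds and a large-sample run at n = 10,000; self-similarity at
n = 20,000 with an equal-size replicate pair as the noise floor;
contrast calibration over 200 replicate 16-tip trees; GLS oracle on 4–8
tip trees.  These sizes put Monte-Carlo error well below every tolerance
asserted while keeping the full suite in the tens of seconds.  Degenerate
inputs (coincident or collinear landmarks, singular metrics, zero-variance
blocks, polytomies) raise typed exceptions rather than warnings, on the
view that a silent fallback in registration code corrupts everything
downstream.

## Known limitations

- Semilandmarks are parsed-and-skipped only; no sliding.
- No maximum-likelihood rotation variant; superposition is least-squares.
- 2D only for the canonical frame, GPA and warps; 3D support is limited to
  nuisance projection and the squared-BE deflation rule.
- The uniform term is annotated, never placed on the BE–PWV plot.
- Wishart-based inference for covariance comparisons is out of scope; the
  covariance distance is descriptive.
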