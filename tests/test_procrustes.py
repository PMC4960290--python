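import numpy as np
import pytest
from scipy.optimize import minimize

from asymmorph.errors import DegeneracyError
from asymmorph.io_landmarks import LandmarkConfiguration, LandmarkSample
from asymmorph.procrustes import (
    boas_allometry,
    centroid_size,
    distance_gradient,
    gpa,
    procrustes_distance,
    project_to_shape_space,
    standardize_mean,
)
from asymmorph.synthetic import IsotropicModel, sample_isotropic


def _config(coords, labels=None, sid="x"):
    coords = np.asarray(coords, float)
    if labels is None:
        labels = [f"L{i+1}" for i in range(coords.shape[0])]
    return LandmarkConfiguration(coords, labels, sid)


def _jitter(coords, rng):
    """Random similarity transform (rotation, scale, translation)."""
    th = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return rng.uniform(0.5, 2.0) * (coords @ R.T) + rng.normal(size=2)


class TestStandardizeMean:
    def test_four_point_cross_rows(self):
        # (±1/2, 0), (0, ±1/2) is already centered with unit size; the J rows
        # are forced by the construction with k = 4
        cfg = _config([[0.5, 0], [0, 0.5], [-0.5, 0], [0, -0.5]])
        ref = standardize_mean(cfg)
        half = 0.5
        np.testing.assert_allclose(ref.J[0], [half, 0] * 4, atol=1e-12)
        np.testing.assert_allclose(ref.J[1], [0, half] * 4, atol=1e-12)
        x, y = ref.mu[0::2], ref.mu[1::2]
        np.testing.assert_allclose(ref.J[3], ref.mu, atol=1e-12)
        np.testing.assert_allclose(ref.J[2][0::2], -y, atol=1e-12)
        np.testing.assert_allclose(ref.J[2][1::2], x, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_standardization_constraints(self, seed):
        rng = np.random.default_rng(seed)
        ref = standardize_mean(_config(rng.normal(size=(8, 2))))
        x, y = ref.mu[0::2], ref.mu[1::2]
        assert abs(x.sum()) < 1e-12
        assert abs(y.sum()) < 1e-12
        assert abs((x * y).sum()) < 1e-12
        assert abs((ref.mu**2).sum() - 1) < 1e-12

    def test_j_rows_orthonormal_random_decagon(self):
        rng = np.random.default_rng(42)
        ref = standardize_mean(_config(rng.normal(size=(10, 2))))
        np.testing.assert_allclose(ref.J @ ref.J.T, np.eye(4), atol=1e-10)

    def test_collinear_rejected(self):
        cfg = _config([[0, 0], [1, 0], [2, 0], [3, 0]])
        with pytest.raises(DegeneracyError):
            standardize_mean(cfg)

    def test_frame_reproducible_under_similarity(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(7, 2))
        ref1 = standardize_mean(_config(coords))
        ref2 = standardize_mean(_config(_jitter(coords, rng)))
        np.testing.assert_allclose(ref1.mu, ref2.mu, atol=1e-9)


class TestProjection:
    def test_mean_projects_to_zero(self, decagon_ref):
        out = project_to_shape_space(decagon_ref.mu, decagon_ref)
        np.testing.assert_allclose(out, 0, atol=1e-12)

    def test_idempotent(self, decagon_ref):
        rng = np.random.default_rng(1)
        c = rng.normal(size=decagon_ref.mu.size)
        once = project_to_shape_space(c, decagon_ref)
        twice = project_to_shape_space(once, decagon_ref)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_translation_invariance(self, decagon_ref):
        rng = np.random.default_rng(2)
        c = rng.normal(size=decagon_ref.mu.size)
        t, s = rng.normal(size=2)
        shift = np.tile([t, s], decagon_ref.k)
        np.testing.assert_allclose(
            project_to_shape_space(c + shift, decagon_ref),
            project_to_shape_space(c, decagon_ref),
            atol=1e-12,
        )


class TestCentroidSize:
    def test_standardized_mean_has_unit_size(self, decagon_ref):
        assert abs(centroid_size(decagon_ref.configuration()) - 1) < 1e-12

    def test_linear_homogeneity(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(6, 2))
        assert np.isclose(centroid_size(_config(2 * coords)), 2 * centroid_size(_config(coords)))

    def test_unit_square(self):
        # four corners at distance sqrt(1/2) from the center: sqrt(4 * 1/2)
        cfg = _config([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert np.isclose(centroid_size(cfg), np.sqrt(2))

    def test_coincident_points_rejected(self):
        with pytest.raises(DegeneracyError):
            centroid_size(_config(np.ones((4, 2)), list("abcd")))


class TestGPA:
    def test_exact_fit_on_copies(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(6, 2))
        copies = [_config(_jitter(coords, rng), sid=f"s{i}") for i in range(5)]
        fit = gpa(LandmarkSample(copies))
        # all deviations vanish; aligned forms equal the standardized form
        assert np.max(np.abs(fit.shape_coords)) < 1e-9
        assert float(np.var(fit.shape_coords)) < 1e-18
        ref_mu = standardize_mean(copies[0]).mu
        np.testing.assert_allclose(fit.aligned, np.tile(ref_mu, (5, 1)), atol=1e-9)

    def test_shape_coords_annihilated_by_j(self):
        rng = np.random.default_rng(6)
        model = IsotropicModel(standardize_mean(_config(rng.normal(size=(8, 2)))).mu, 0.01)
        fit = gpa(sample_isotropic(model, 20, seed=7))
        resid = fit.shape_coords @ fit.reference.J.T
        assert np.max(np.abs(resid)) < 1e-8

    def test_agrees_with_one_step_projection_to_second_order(self):
        sigma = 0.001
        rng = np.random.default_rng(8)
        ref = standardize_mean(_config(rng.normal(size=(9, 2))))
        model = IsotropicModel(ref.mu, sigma)
        sample = sample_isotropic(model, 30, seed=9)
        fit = gpa(sample)
        one_step = project_to_shape_space(sample.as_matrix() - ref.mu, ref)
        one_step -= one_step.mean(axis=0)
        assert np.max(np.abs(fit.shape_coords - one_step)) < 50 * sigma**2

    def test_boas_preserves_centroid_sizes(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(7, 2))
        sample = LandmarkSample(
            [_config(_jitter(coords, rng) + rng.normal(scale=0.01, size=(7, 2)), sid=f"s{i}") for i in range(6)]
        )
        fit = gpa(sample, scale=False)
        input_cs = [centroid_size(c) for c in sample]
        fitted_cs = [
            centroid_size(_config(v.reshape(-1, 2))) for v in fit.aligned
        ]
        np.testing.assert_allclose(fitted_cs, input_cs, rtol=1e-10)
        # Boas: only rows 1-3 annihilated, scale direction retained
        resid = fit.shape_coords @ fit.reference.J[:3].T
        assert np.max(np.abs(resid)) < 1e-8


def _brute_force_distance(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean(0)
    ac = ac / np.sqrt((ac**2).sum())
    bc = b - b.mean(0)

    def obj(p):
        s, th, tx, ty = p
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return np.sum((ac - (s * (bc @ R.T) + np.array([tx, ty]))) ** 2)

    best = np.inf
    for th0 in (0.0, np.pi / 2, np.pi, -np.pi / 2):
        r = minimize(
            obj,
            [1.0, th0, 0.0, 0.0],
            method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-16, maxiter=5000),
        )
        best = min(best, r.fun)
    return float(np.sqrt(best))


class TestProcrustesDistance:
    def test_self_distance_zero(self, decagon_ref):
        a = decagon_ref.configuration()
        assert procrustes_distance(a, a) == pytest.approx(0, abs=1e-12)

    def test_local_mode_symmetric(self, decagon_ref):
        rng = np.random.default_rng(11)
        d = project_to_shape_space(rng.normal(size=20), decagon_ref)
        d /= np.linalg.norm(d)
        a = _config(decagon_ref.coords + 0.05 * d.reshape(-1, 2))
        b = _config(decagon_ref.coords - 0.07 * d.reshape(-1, 2))
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12
        )

    def test_matches_brute_force_minimum(self, decagon_ref):
        rng = np.random.default_rng(12)
        for _ in range(10):
            d = project_to_shape_space(rng.normal(size=20), decagon_ref)
            d /= np.linalg.norm(d)
            amp = rng.uniform(0.02, 0.2)
            a = decagon_ref.coords + (amp / 2) * d.reshape(-1, 2)
            b = decagon_ref.coords - (amp / 2) * d.reshape(-1, 2)
            A = _config(_jitter(a, rng))
            B = _config(_jitter(b, rng))
            d_loc = procrustes_distance(A, B, mode="local")
            d_bf = _brute_force_distance(A.coords, B.coords)
            assert abs(d_loc - d_bf) / d_bf < 1e-3

    def test_reference_mode_requires_ref(self, decagon_ref):
        a = decagon_ref.configuration()
        with pytest.raises(ValueError):
            procrustes_distance(a, a, mode="reference")


class TestBoasAllometry:
    def _growth_sample(self, ref, scales, tangential_idx=None, angle=0.0, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        configs = []
        for i, c in enumerate(scales):
            coords = c * ref.coords.copy()
            if tangential_idx is not None:
                # this landmark's growth direction is rotated off-radial
                pos = ref.coords[tangential_idx]
                r = np.linalg.norm(pos)
                radial = pos / r
                tang = np.array([-radial[1], radial[0]])
                coords[tangential_idx] = c * r * (
                    np.cos(angle) * radial + np.sin(angle) * tang
                )
            coords += rng.normal(scale=sigma, size=coords.shape)
            configs.append(LandmarkConfiguration(coords, ref.labels, f"s{i}"))
        return LandmarkSample(configs)

    def test_exact_isotropic_growth_is_radial(self, decagon_ref):
        scales = np.linspace(0.8, 1.2, 20)
        sample = self._growth_sample(decagon_ref, scales)
        fit = gpa(sample, scale=False)
        res = boas_allometry(fit, fit.centroid_sizes)
        assert np.max(res.misalignment) < 1e-6
        # slope magnitude proportional to distance from centroid
        dists = np.linalg.norm(res.mean_positions - res.mean_positions.mean(0), axis=1)
        mags = np.linalg.norm(res.slopes, axis=1)
        ratio = mags / dists
        assert np.ptp(ratio) / ratio.mean() < 1e-6

    def test_recovers_injected_tangential_angle(self, decagon_ref):
        # allometric field: radial growth everywhere plus a tangential extra
        # at landmark 3, so its growth direction sits 25 degrees off radial
        rng = np.random.default_rng(21)
        angle = np.deg2rad(25.0)
        idx = 3
        pos = decagon_ref.coords[idx]
        r = np.linalg.norm(pos)
        radial = pos / r
        tang = np.array([-radial[1], radial[0]])
        field = decagon_ref.mu.copy()  # isotropic radial growth
        field[2 * idx : 2 * idx + 2] += np.tan(angle) * r * tang
        # expected angle after removing what the Boas registration absorbs
        # (centering + rotation: rows 1-3 of J)
        J3 = decagon_ref.J[:3]
        f_reg = field - J3.T @ (J3 @ field)
        f3 = f_reg[2 * idx : 2 * idx + 2]
        expected = np.arccos(np.clip(f3 @ radial / np.linalg.norm(f3), -1, 1))
        scales = 1.0 + 0.1 * rng.standard_normal(200)
        configs = [
            LandmarkConfiguration(
                (decagon_ref.mu + (c - 1.0) * field).reshape(-1, 2)
                + rng.normal(scale=0.005, size=(10, 2)),
                decagon_ref.labels,
                f"s{i}",
            )
            for i, c in enumerate(scales)
        ]
        fit = gpa(LandmarkSample(configs), scale=False)
        res = boas_allometry(fit, fit.centroid_sizes)
        assert abs(np.rad2deg(res.misalignment[idx] - expected)) < 2.0
        assert np.rad2deg(res.misalignment[idx]) > 10.0  # the signal is there

    def test_permuted_size_gives_null_slopes(self, decagon_ref):
        rng = np.random.default_rng(23)
        scales = np.linspace(0.8, 1.2, 100)
        sample = self._growth_sample(decagon_ref, scales, sigma=0.002, seed=24)
        fit = gpa(sample, scale=False)
        res = boas_allometry(fit, fit.centroid_sizes)
        perm = rng.permutation(fit.centroid_sizes)
        res_perm = boas_allometry(fit, perm)
        mags = np.linalg.norm(res.slopes, axis=1)
        mags_perm = np.linalg.norm(res_perm.slopes, axis=1)
        assert np.median(mags_perm) < 0.1 * np.median(mags)

    def test_requires_boas_fit(self, decagon_ref):
        sample = sample_isotropic(IsotropicModel(decagon_ref.mu, 0.01), 10, seed=1)
        fit = gpa(sample, scale=True)
        with pytest.raises(ValueError):
            boas_allometry(fit, fit.centroid_sizes)


class TestDistanceGradient:
    def test_orthogonal_to_j_rows(self, decagon_ref):
        v = distance_gradient(decagon_ref, ("L1", "L5"))
        np.testing.assert_allclose(decagon_ref.J @ v, 0, atol=1e-12)
        assert np.isclose(np.linalg.norm(v), 1.0)

    def test_finite_difference_directional_derivative(self, decagon_ref):
        labels = decagon_ref.labels
        ia, ib = 0, 4
        v = distance_gradient(decagon_ref, (labels[ia], labels[ib]))
        g = np.zeros(2 * decagon_ref.k)
        pa, pb = decagon_ref.coords[ia], decagon_ref.coords[ib]
        u = (pa - pb) / np.linalg.norm(pa - pb)
        g[2 * ia : 2 * ia + 2] = u
        g[2 * ib : 2 * ib + 2] = -u
        expected = float(g @ v)  # derivative of the distance along v
        assert expected > 0
        eps = 1e-6

        def dist(vec):
            c = vec.reshape(-1, 2)
            return np.linalg.norm(c[ia] - c[ib])

        fd = (dist(decagon_ref.mu + eps * v) - dist(decagon_ref.mu - eps * v)) / (2 * eps)
        assert abs(fd - expected) < 1e-6

    def test_antisymmetric_under_label_swap(self):
        cfg = _config([[0.5, 0], [0, 0.5], [-0.5, 0], [0, -0.5]])
        ref = standardize_mean(cfg)
        v1 = distance_gradient(ref, (ref.labels[0], ref.labels[2]))
        v2 = distance_gradient(ref, (ref.labels[2], ref.labels[0]))
        np.testing.assert_allclose(v1, v2, atol=1e-12)  # distance is symmetric
        with pytest.raises(ValueError):
            distance_gradient(ref, (ref.labels[0], ref.labels[0]))
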