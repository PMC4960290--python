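import numpy as np
import pytest

from asymmorph.errors import StructuralError
from asymmorph.io_landmarks import LandmarkSample
from asymmorph.phylo_contrasts import (
    Phylogeny,
    contrast_relative_warps,
    felsenstein_contrasts,
    neutrality_scan,
    shape_contrasts,
)
from asymmorph.procrustes import project_to_shape_space, standardize_mean
from asymmorph.synthetic import (
    brownian_tree_shapes,
    grid_config,
    random_phylogeny,
)


def _tip_sample(tree, root, rate, seed):
    return brownian_tree_shapes(tree, root, rate, seed=seed)


class TestRecursion:
    def test_two_tip_closed_form(self):
        tree = Phylogeny.from_newick_string("(A:1.5,B:0.5);")
        vals = np.array([[2.0, 4.0], [0.0, 1.0]])  # rows: A, B (tip order)
        C, dur, node_means, W = felsenstein_contrasts(tree, vals)
        assert C.shape == (1, 2)
        np.testing.assert_allclose(dur, [2.0])
        np.testing.assert_allclose(C[0], (vals[0] - vals[1]) / np.sqrt(2.0))
        # ancestral value: branch-length weighted average (t2*A + t1*B)/(t1+t2)
        root_val = node_means[tree.root]
        np.testing.assert_allclose(root_val, (0.5 * vals[0] + 1.5 * vals[1]) / 2.0)

    @pytest.mark.parametrize("n_tips,seed", [(4, 0), (6, 1), (8, 2)])
    def test_gls_oracle_small_trees(self, n_tips, seed):
        """The recursion's contrasts whiten the Brownian tip covariance and
        its root value is the GLS mean, checked against the explicit
        shared-branch-length covariance matrix."""
        tree = random_phylogeny(n_tips, seed=seed)
        rng = np.random.default_rng(seed + 10)
        vals = rng.standard_normal((n_tips, 3))
        C, dur, node_means, W = felsenstein_contrasts(tree, vals)
        assert C.shape[0] == n_tips - 1
        assert np.all(dur > 0)
        V = tree.shared_path_covariance()
        np.testing.assert_allclose(W @ V @ W.T, np.eye(n_tips - 1), atol=1e-9)
        # root estimate equals the GLS mean under Brownian covariance
        ones = np.ones(n_tips)
        Vi = np.linalg.inv(V)
        gls_root = (ones @ Vi @ vals) / (ones @ Vi @ ones)
        np.testing.assert_allclose(node_means[tree.root], gls_root, atol=1e-9)
        # unnormalized durations: contrast variances under unit-rate Brownian
        C_u, dur_u, _, W_u = felsenstein_contrasts(tree, vals, normalize=False)
        np.testing.assert_allclose(np.diag(W_u @ V @ W_u.T), dur_u, atol=1e-9)


class TestShapeContrasts:
    def test_tip_name_mismatch_rejected(self):
        tree = random_phylogeny(4, seed=3)
        root = grid_config(3, 3)
        sample = _tip_sample(tree, root, 1e-4, seed=4)
        sample.configurations[0].specimen_id = "wrong"
        with pytest.raises(StructuralError):
            shape_contrasts(tree, sample)

    def test_identical_tips_give_zero_contrasts_both_modes(self):
        tree = random_phylogeny(5, seed=5)
        root = grid_config(3, 3)
        sample = _tip_sample(tree, root, 0.0, seed=6)
        cs_plain = shape_contrasts(tree, sample, recenter=False)
        cs_rec = shape_contrasts(tree, sample, recenter=True)
        assert np.max(np.abs(cs_plain.contrasts)) < 1e-10
        assert np.max(np.abs(cs_rec.contrasts)) < 1e-10

    def test_recentering_agrees_to_first_order_at_low_dispersion(self):
        tree = random_phylogeny(8, seed=7)
        root = grid_config(3, 3)
        # dispersion ~0.01 in shape distance
        sample = _tip_sample(tree, root, 1e-6, seed=8)
        cs_plain = shape_contrasts(tree, sample, recenter=False)
        cs_rec = shape_contrasts(tree, sample, recenter=True)
        scale = np.linalg.norm(cs_plain.contrasts)
        rel = np.linalg.norm(cs_rec.contrasts - cs_plain.contrasts) / scale
        assert rel < 0.05
        assert cs_rec.per_contrast_J is not None
        assert len(cs_rec.per_contrast_J) == cs_rec.contrasts.shape[0]

    def test_brownian_calibration_contrast_variance(self):
        # over replicate trees, normalized raw-coordinate contrasts have
        # variance equal to the generating rate
        rate = 1e-4
        root = grid_config(3, 3)
        p = 2 * root.k
        all_c = []
        for seed in range(50):
            tree = random_phylogeny(8, seed=100 + seed)
            tips = brownian_tree_shapes(tree, root, rate, seed=200 + seed)
            C, _, _, _ = felsenstein_contrasts(tree, tips.as_matrix())
            all_c.append(C)
        C = np.concatenate(all_c)
        var = C.var(ddof=0)
        m = C.size
        se = rate * np.sqrt(2.0 / m)
        assert abs(var - rate) < 3 * se


class TestContrastRelativeWarps:
    def test_proportional_contrasts_single_axis(self):
        tree = random_phylogeny(6, seed=9)
        root = grid_config(3, 3)
        sample = _tip_sample(tree, root, 1e-5, seed=10)
        cs = shape_contrasts(tree, sample)
        ref = cs.grand_mean
        rng = np.random.default_rng(11)
        v = project_to_shape_space(rng.standard_normal(2 * root.k), ref)
        v /= np.linalg.norm(v)
        cs.contrasts = np.outer(rng.standard_normal(cs.contrasts.shape[0]), v)
        rw = contrast_relative_warps(cs, 1)
        assert abs(rw.axes[0] @ v) > 1 - 1e-10

    def test_axes_orthonormal_scores_uncorrelated(self):
        tree = random_phylogeny(10, seed=12)
        root = grid_config(3, 3)
        sample = _tip_sample(tree, root, 1e-4, seed=13)
        cs = shape_contrasts(tree, sample)
        rw = contrast_relative_warps(cs, 4)
        np.testing.assert_allclose(rw.axes @ rw.axes.T, np.eye(4), atol=1e-10)
        G = rw.contrast_scores.T @ rw.contrast_scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-10)

    def test_anisotropic_rate_leading_axis_recovery(self):
        root = grid_config(3, 3)
        ref = standardize_mean(root)
        rng = np.random.default_rng(14)
        lead = project_to_shape_space(rng.standard_normal(2 * root.k), ref)
        lead /= np.linalg.norm(lead)
        base = 1e-5
        rate = base * np.eye(2 * root.k) + 9 * base * np.outer(lead, lead)  # 10:1
        tree = random_phylogeny(64, seed=15)
        tips = brownian_tree_shapes(tree, root, rate, seed=16)
        cs = shape_contrasts(tree, tips)
        rw = contrast_relative_warps(cs, 1)
        # compare in the fitted frame: project the injected axis to shape space
        lead_fit = project_to_shape_space(lead, cs.grand_mean)
        lead_fit /= np.linalg.norm(lead_fit)
        assert abs(rw.axes[0] @ lead_fit) > 0.95

    def test_n_axes_exceeding_rank_rejected(self):
        tree = random_phylogeny(4, seed=17)
        root = grid_config(3, 3)
        cs = shape_contrasts(tree, _tip_sample(tree, root, 1e-4, seed=18))
        with pytest.raises(ValueError):
            contrast_relative_warps(cs, 5)  # only 3 contrasts


class TestNeutralityScan:
    def test_r0_equals_plain_shape_distances(self):
        tree = random_phylogeny(6, seed=19)
        root = grid_config(3, 3)
        sample = _tip_sample(tree, root, 1e-4, seed=20)
        cs = shape_contrasts(tree, sample)
        levels = neutrality_scan(tree, sample, cs, max_removed=1)
        D = cs.tip_shape_coords
        iu = np.triu_indices(D.shape[0], 1)
        plain = np.sqrt(((D[:, None] - D[None, :]) ** 2).sum(-1))[iu]
        np.testing.assert_allclose(levels[0].distances, plain, atol=1e-12)

    def test_brownian_squared_distance_linear_in_time(self):
        root = grid_config(3, 3)
        tree = random_phylogeny(64, seed=21)
        tips = brownian_tree_shapes(tree, root, 1e-5, seed=22)
        levels = neutrality_scan(tree, tips, max_removed=2)
        for lv in levels:
            assert lv.r2_sq > 0.5

    def test_winnowing_removes_injected_functional_direction(self):
        root = grid_config(3, 3)
        ref = standardize_mean(root)
        rng = np.random.default_rng(23)
        f = project_to_shape_space(rng.standard_normal(2 * root.k), ref)
        f /= np.linalg.norm(f)
        tree = random_phylogeny(64, seed=24)
        tips = brownian_tree_shapes(tree, root, 1e-6, seed=25)
        # one large non-clocklike direction: iid per-tip displacement along f
        mat = tips.as_matrix() + np.outer(rng.standard_normal(64) * 0.02, f)
        noisy = LandmarkSample.from_matrix(mat, tips.labels, 2, [c.specimen_id for c in tips])
        levels = neutrality_scan(tree, noisy, max_removed=2)
        # removing the first contrast axis restores clocklike linearity
        assert levels[1].r2_sq > levels[0].r2_sq

    def test_patristic_cap_restricts_pairs(self):
        tree = random_phylogeny(10, seed=26)
        root = grid_config(3, 3)
        tips = brownian_tree_shapes(tree, root, 1e-5, seed=27)
        pat = tree.patristic_distance_matrix()
        cap = float(np.median(pat[np.triu_indices(10, 1)]))
        levels = neutrality_scan(tree, tips, max_removed=1, patristic_cap=cap)
        assert np.all(levels[0].patristic < cap)

    def test_max_removed_must_be_below_rank(self):
        tree = random_phylogeny(4, seed=28)
        root = grid_config(3, 3)
        tips = brownian_tree_shapes(tree, root, 1e-5, seed=29)
        with pytest.raises(ValueError):
            neutrality_scan(tree, tips, max_removed=3)  # rank is 3
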