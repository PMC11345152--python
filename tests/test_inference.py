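"""Back-projection, SimBaS scores, joint bands and cluster extraction."""

import numpy as np
import pytest

from cpfosr.cp import CPBasis, build_basis
from cpfosr.fosr import PosteriorDraws
from cpfosr.inference import (BackprojectedStats, backproject_stats,
                              flag_clusters, joint_bands, simbas_map)


def _tiny_basis(L):
    """CPBasis whose basis matrix is exactly L (R x Nv), on a (Nv,1,1) grid."""
    R, nv = L.shape
    cp = CPBasis(R=R, lam=np.ones(R), A1=np.eye(nv)[:, :R],
                 A2=np.ones((1, R)), A3=np.ones((1, R)),
                 G=np.zeros((2, R)), fit_rel_error=0.0,
                 spatial_shape=(nv, 1, 1))
    build_basis(cp)
    cp.L = np.asarray(L, float)
    cp.P = np.linalg.pinv(cp.L)
    return cp


def _draws_from_gamma(gammas):
    g = np.asarray(gammas, float)
    M, p, R = g.shape
    return PosteriorDraws(gamma_star=g, sigma_eps=np.tile(np.eye(R), (M, 1, 1)),
                          M=M)


def _manual_stats(c_hat, c_sd, z):
    c_hat = np.asarray(c_hat, float)
    c_sd = np.asarray(c_sd, float)
    z = np.asarray(z, float)
    return BackprojectedStats(contrast=np.array([1.0]), c_hat=c_hat, c_sd=c_sd,
                              z_stats=z, eligible=c_sd > 0, degenerate=False,
                              M=len(z))


class TestBackproject:
    def test_three_draw_two_voxel_hand_enumeration(self):
        L = np.array([[1.0, 2.0]])  # R=1, 2 voxels
        cp = _tiny_basis(L)
        draws = _draws_from_gamma(np.array([[[1.0]], [[2.0]], [[3.0]]]))
        stats = backproject_stats(draws, cp, [1.0])
        # C(m) = gamma_m * L: voxel maps (1,2), (2,4), (3,6)
        np.testing.assert_allclose(stats.c_hat, [2.0, 4.0])
        np.testing.assert_allclose(stats.c_sd, [1.0, 2.0])
        # standardized deviations are identical across voxels: |m-2|
        np.testing.assert_allclose(np.sort(stats.z_stats), [0.0, 1.0, 1.0])

    def test_chunked_and_unchunked_agree(self, rng):
        L = rng.standard_normal((3, 500))
        cp = _tiny_basis(L)
        draws = _draws_from_gamma(rng.standard_normal((50, 2, 3)))
        a = backproject_stats(draws, cp, [1.0, -1.0], chunk_size=7)
        b = backproject_stats(draws, cp, [1.0, -1.0], chunk_size=10**9)
        np.testing.assert_allclose(a.c_hat, b.c_hat, atol=1e-12)
        np.testing.assert_allclose(a.c_sd, b.c_sd, atol=1e-12)
        np.testing.assert_allclose(a.z_stats, b.z_stats, atol=1e-12)

    def test_identical_draws_degenerate(self):
        cp = _tiny_basis(np.array([[1.0, 2.0]]))
        draws = _draws_from_gamma(np.tile([[2.0]], (5, 1, 1)))
        stats = backproject_stats(draws, cp, [1.0])
        assert stats.degenerate
        assert not stats.eligible.any()
        np.testing.assert_array_equal(simbas_map(stats), [1.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            joint_bands(stats, 0.05)

    def test_contrast_length_checked(self):
        cp = _tiny_basis(np.array([[1.0, 2.0]]))
        draws = _draws_from_gamma(np.zeros((3, 2, 1)))
        with pytest.raises(ValueError, match="contrast length"):
            backproject_stats(draws, cp, [1.0])


class TestSimBaS:
    def test_zero_mean_voxel_scores_one(self):
        stats = _manual_stats([0.0, 1.0], [1.0, 1.0], [0.5, 1.5])
        p = simbas_map(stats)
        assert p[0] == 1.0

    def test_direct_count_example(self):
        # z = {1,2,3,4}, |Chat|/sd = 2.5 -> 2 of 4 satisfy 2.5 <= z
        stats = _manual_stats([2.5], [1.0], [1.0, 2.0, 3.0, 4.0])
        assert simbas_map(stats)[0] == 0.5

    def test_scores_are_multiples_of_one_over_m(self, rng):
        stats = _manual_stats(rng.standard_normal(50),
                              np.abs(rng.standard_normal(50)) + 0.1,
                              np.abs(rng.standard_normal(64)))
        p = simbas_map(stats)
        np.testing.assert_allclose(p * 64, np.round(p * 64), atol=1e-9)

    def test_band_inversion_duality_over_alpha_grid(self, rng):
        """min{alpha on the 1/M grid : 0 not in I_alpha(v)} equals P_SimBaS
        exactly: P <= alpha <=> the joint band excludes zero."""
        M = 64
        stats = _manual_stats(rng.standard_normal(200),
                              np.abs(rng.standard_normal(200)) + 0.05,
                              np.abs(rng.standard_normal(M)))
        p = simbas_map(stats)
        for j in range(1, M):
            alpha = j / M
            lo, hi = joint_bands(stats, alpha)
            excluded = (lo > 0) | (hi < 0)
            np.testing.assert_array_equal(p <= alpha, excluded)


class TestJointBands:
    def test_order_statistic_convention(self):
        stats = _manual_stats([0.0], [1.0], [1.0, 2.0, 3.0, 4.0])
        lo, hi = joint_bands(stats, 0.25)  # ceil(0.75*4) = 3rd order stat = 3
        assert np.isclose(hi[0] - lo[0], 2 * 3.0)

    def test_bands_nested_in_alpha(self, rng):
        stats = _manual_stats(rng.standard_normal(100),
                              np.abs(rng.standard_normal(100)) + 0.1,
                              np.abs(rng.standard_normal(200)))
        lo1, hi1 = joint_bands(stats, 0.01)
        lo2, hi2 = joint_bands(stats, 0.10)
        assert (lo1 <= lo2 + 1e-12).all() and (hi1 >= hi2 - 1e-12).all()

    def test_alpha_too_small_for_m_raises(self):
        stats = _manual_stats([0.0], [1.0], np.ones(4))
        with pytest.raises(ValueError, match="alpha"):
            joint_bands(stats, 1e-9)
        with pytest.raises(ValueError):
            joint_bands(stats, 1.5)


def _flood_fill_labels(flagged, connectivity):
    """Independent brute-force BFS labeling oracle."""
    offsets = []
    for d in np.ndindex(3, 3, 3):
        off = tuple(x - 1 for x in d)
        if off == (0, 0, 0):
            continue
        order = sum(abs(x) for x in off)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offsets.append(off)
    labels = np.zeros(flagged.shape, int)
    nxt = 0
    for start in zip(*np.nonzero(flagged)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            cur = stack.pop()
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nb, flagged.shape)):
                    if flagged[nb] and not labels[nb]:
                        labels[nb] = nxt
                        stack.append(nb)
    return labels


class TestFlagClusters:
    def test_size_threshold_keeps_only_large_component(self):
        p = np.ones((10, 10, 10))
        p[0:5, 0:5, 0:6] = 0.001  # 5*5*6 = 150 >= 125
        p[8:10, 8:10, 0:5] = 0.001  # 2*2*5 = 20 < 125
        table, labels = flag_clusters(p, alpha=0.01, min_size=125)
        assert len(table) == 1
        assert table.iloc[0]["size"] == 150
        assert (labels > 0).sum() == 150

    def test_constructed_130_and_60_voxel_components(self):
        p = np.ones((12, 12, 12))
        block = np.zeros((12, 12, 12), bool)
        block[0:13, 0:2, 0:5] = True  # 12*2*5 = 120
        block[0:10, 2, 0] = True  # +10 connected -> 130
        p[block] = 0.001
        p[8:12, 8:11, 7:12] = 0.001  # 4*3*5 = 60, disjoint
        table, _ = flag_clusters(p, alpha=0.01, min_size=125)
        assert len(table) == 1
        assert table.iloc[0]["size"] == 130

    def test_all_clear_gives_empty_table(self):
        table, labels = flag_clusters(np.ones((5, 5, 5)), alpha=0.01,
                                      min_size=1)
        assert len(table) == 0
        assert (labels == 0).all()

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        flagged = rng.random((12, 12, 12)) < 0.3
        p = np.where(flagged, 0.0, 1.0)
        table, labels = flag_clusters(p, alpha=0.5, min_size=1,
                                      connectivity=connectivity)
        oracle = _flood_fill_labels(flagged, connectivity)
        assert labels.astype(bool).sum() == flagged.sum()
        # same partition: label images agree up to renaming
        pairs = set(zip(labels.ravel(), oracle.ravel()))
        assert len({a for a, b in pairs if a}) == len({b for a, b in pairs if b})
        assert len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            flag_clusters(np.ones((3, 3, 3)), connectivity=8)


class TestSimbasInference:
    def test_flagged_set_shrinks_as_alpha_decreases(self, small_fit):
        _, _, _, res = small_fit
        big = res.simbas("intercept", alpha=0.10, min_size=1)
        small = res.simbas("intercept", alpha=0.01, min_size=1)
        assert small.flagged.sum() <= big.flagged.sum()
        assert set(zip(*np.nonzero(small.flagged))) <= set(
            zip(*np.nonzero(big.flagged)))

    def test_result_shapes_and_invariants(self, small_fit):
        y, _, _, res = small_fit
        out = res.simbas("intercept", alpha=0.05, min_size=1)
        assert out.c_hat.shape == y.spatial_shape
        assert np.all((out.p_simbas >= 0) & (out.p_simbas <= 1))
        assert np.all(out.p_simbas[out.flagged] < 0.05)
        assert out.n_active_voxels() == (out.cluster_labels > 0).sum()
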