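"""CP-ALS decomposition, weight normalization, basis and projector."""

import numpy as np
import pytest

from cpfosr.cp import (CPBasis, build_basis, cp_decompose, project,
                       reconstruct, spatial_basis_full)
from cpfosr.simulate import gen_multisubject
from cpfosr.tensor import ContrastTensor, fold, khatri_rao, unfold


def _basis_from_factors(lam, A1, A2, A3, G):
    cp = CPBasis(R=len(lam), lam=np.asarray(lam, float), A1=A1, A2=A2, A3=A3,
                 G=G, fit_rel_error=0.0,
                 spatial_shape=(A1.shape[0], A2.shape[0], A3.shape[0]))
    return build_basis(cp)


def _random_cp(rng, dims, N, R):
    def unit(d):
        a = rng.standard_normal((d, R))
        return a / np.linalg.norm(a, axis=0)

    return _basis_from_factors(
        rng.uniform(1.0, 2.0, R), unit(dims[0]), unit(dims[1]), unit(dims[2]),
        rng.standard_normal((N, R)),
    )


class TestCPDecompose:
    def test_all_ones_tensor_is_rank_one(self):
        """The all-ones 2x3x4x2 tensor is an outer product of ones vectors:
        every factor column is 1/sqrt(dim) and the weight carries the full
        tensor norm, lam_1 = sqrt(2*3*4*2) = sqrt(48)."""
        cp = cp_decompose(np.ones((2, 3, 4, 2)), R=1, seed=0)
        assert cp.fit_rel_error < 1e-10
        assert np.isclose(cp.lam[0], np.sqrt(48))
        for A, d in ((cp.A1, 2), (cp.A2, 3), (cp.A3, 4), (cp.G, 2)):
            np.testing.assert_allclose(A[:, 0], np.full(d, 1 / np.sqrt(d)),
                                       atol=1e-8)

    def test_exact_rank3_tensor_recovered(self, rng):
        y, _, truth = gen_multisubject(dims=(8, 9, 10), N=12, R_true=3,
                                       sigma_voxel=0.0, seed=5)
        cp = cp_decompose(y, R=3, seed=5)
        assert cp.fit_rel_error < 1e-6
        np.testing.assert_allclose(reconstruct(cp), y.data, atol=1e-6)

    def test_error_monotone_in_rank(self):
        y, _, _ = gen_multisubject(dims=(8, 8, 8), N=10, R_true=3,
                                   sigma_voxel=0.0, seed=6)
        e2 = cp_decompose(y, R=2, n_restarts=5, seed=1).fit_rel_error
        e3 = cp_decompose(y, R=3, n_restarts=5, seed=1).fit_rel_error
        assert e2 >= e3

    def test_unit_norm_columns_and_nonnegative_weights(self):
        y, _, _ = gen_multisubject(dims=(6, 7, 8), N=9, R_true=2, seed=8)
        cp = cp_decompose(y, R=2, seed=8)
        for A in (cp.A1, cp.A2, cp.A3):
            np.testing.assert_allclose(np.linalg.norm(A, axis=0), 1.0,
                                       atol=1e-10)
        assert (cp.lam >= 0).all()

    def test_reconstruction_error_invariant_to_component_permutation(self, rng):
        cp = _random_cp(rng, (5, 6, 7), 8, 3)
        x = reconstruct(cp)
        perm = [2, 0, 1]
        cp_perm = _basis_from_factors(cp.lam[perm], cp.A1[:, perm],
                                      cp.A2[:, perm], cp.A3[:, perm],
                                      cp.G[:, perm])
        np.testing.assert_allclose(reconstruct(cp_perm), x, atol=1e-10)
        # sign flips absorbed pairwise leave the tensor unchanged
        s = np.array([-1.0, 1.0, -1.0])
        cp_flip = _basis_from_factors(cp.lam, cp.A1 * s, cp.A2, cp.A3,
                                      cp.G * s)
        np.testing.assert_allclose(reconstruct(cp_flip), x, atol=1e-10)

    def test_non_finite_data_raises(self):
        bad = np.ones((4, 4, 4, 3))
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            cp_decompose(bad, R=1)

    def test_seeded_determinism(self):
        y, _, _ = gen_multisubject(dims=(6, 6, 6), N=8, R_true=2, seed=9)
        a = cp_decompose(y, R=2, seed=3)
        b = cp_decompose(y, R=2, seed=3)
        np.testing.assert_array_equal(a.lam, b.lam)
        np.testing.assert_array_equal(a.G, b.G)

    def test_zero_voxels_give_zero_basis_columns(self):
        """Voxels that are zero across all subjects stay in the fit and give
        zero entries of L there."""
        y, _, _ = gen_multisubject(dims=(6, 6, 6), N=8, R_true=2,
                                   sigma_voxel=0.0, seed=10)
        data = y.data.copy()
        data[0, :, :, :] = 0.0
        cp = cp_decompose(data, R=2, seed=10)
        L3d = spatial_basis_full(cp).reshape(2, 6, 6, 6, order="F")
        np.testing.assert_allclose(np.abs(L3d[:, 0]).max(), 0.0, atol=1e-6)


class TestBuildBasis:
    def test_single_standard_basis_component(self):
        e = lambda d: np.eye(d)[:, :1]
        cp = _basis_from_factors([2.0], e(3), e(4), e(5), np.ones((2, 1)))
        L = cp.L
        assert L.shape == (1, 60)
        assert L[0, 0] == 2.0
        assert np.count_nonzero(L) == 1
        assert np.isclose(cp.P[0, 0], 0.5)
        assert np.count_nonzero(cp.P) == 1

    def test_pseudoinverse_identity_full_row_rank(self, rng):
        cp = _random_cp(rng, (4, 5, 6), 7, 3)
        assert cp.L.shape == (3, 120)
        assert np.abs(cp.L @ cp.P - np.eye(3)).max() < 1e-8

    def test_L_reproducible_from_factors(self, rng):
        cp = _random_cp(rng, (4, 5, 6), 7, 3)
        L = cp.lam[:, None] * khatri_rao([cp.A3, cp.A2, cp.A1]).T
        np.testing.assert_allclose(cp.L, L, atol=1e-12)

    def test_rank_deficient_basis_warns(self):
        a = np.ones((4, 2)) / 2.0  # duplicated columns -> rank-1 L
        cp = CPBasis(R=2, lam=np.ones(2), A1=a, A2=a, A3=a,
                     G=np.ones((3, 2)), fit_rel_error=0.0,
                     spatial_shape=(4, 4, 4))
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            build_basis(cp)
        assert cp.effective_rank == 1


class TestProject:
    def test_zero_tensor_gives_zero_scores(self, rng):
        cp = _random_cp(rng, (4, 5, 6), 7, 2)
        scores = project(np.zeros((4, 5, 6, 7)), cp)
        np.testing.assert_array_equal(scores, np.zeros((7, 2)))

    def test_round_trip_recovers_scores(self, rng):
        cp = _random_cp(rng, (4, 5, 6), 7, 3)
        y = reconstruct(cp)
        np.testing.assert_allclose(project(y, cp), cp.G, atol=1e-8)

    def test_mode4_unfolding_projection_oracle(self, rng):
        """For noiseless Y built from (G, L), (mode-4 subject matrix) @ P = G."""
        cp = _random_cp(rng, (4, 5, 6), 7, 3)
        y = reconstruct(cp)
        np.testing.assert_allclose(unfold(y, 4).T @ cp.P, cp.G, atol=1e-8)

    def test_scores_converge_as_noise_vanishes(self, rng):
        cp = _random_cp(rng, (6, 6, 6), 10, 3)
        y = reconstruct(cp)
        errs = []
        for sigma in (1e-1, 1e-3, 1e-6):
            noisy = y + sigma * np.random.default_rng(0).standard_normal(y.shape)
            errs.append(np.abs(project(noisy, cp) - cp.G).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4

    def test_dimension_mismatch_raises(self, rng):
        cp = _random_cp(rng, (4, 5, 6), 7, 2)
        with pytest.raises(ValueError):
            project(np.zeros((4, 5, 7, 7)), cp)

    def test_masked_projection_consistent_with_masked_basis(self, rng):
        y, _, _ = gen_multisubject(dims=(6, 6, 6), N=8, R_true=2, seed=11)
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        ym = ContrastTensor(y.data, mask=mask)
        cp = cp_decompose(ym, R=2, seed=11)
        assert cp.L.shape[1] == mask.sum()
        scores = project(ym, cp)
        np.testing.assert_allclose(scores, ym.subject_matrix() @ cp.P,
                                   atol=1e-10)
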