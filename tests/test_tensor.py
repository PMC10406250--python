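"""Finite-difference operators and the structure-tensor eigen machinery."""

import numpy as np
import pytest

from aniso4d import (
    EigenSystem,
    RemapConfig,
    TensorField4D,
    divergence4d,
    eigendecompose,
    gradient4d,
    rebuild_tensor,
    remap_eigenvalues,
    steering_tensor,
    structure_tensor,
)


def loop_gradient(values, spacing=(1.0, 1.0, 1.0, 1.0)):
    """Index-by-index forward-difference oracle."""
    g = np.zeros(values.shape + (4,))
    for idx in np.ndindex(values.shape):
        for ax in range(4):
            nxt = list(idx)
            nxt[ax] += 1
            if nxt[ax] < values.shape[ax]:
                g[idx + (ax,)] = (values[tuple(nxt)] - values[idx]) / spacing[ax]
    return g


def neumann_laplacian(values):
    """Explicit 4D Laplacian stencil with replicate-edge boundary."""
    out = np.zeros_like(values, dtype=float)
    for ax in range(4):
        padded = np.concatenate(
            [np.take(values, [0], axis=ax), values, np.take(values, [-1], axis=ax)],
            axis=ax,
        )
        n = values.shape[ax]
        hi = np.take(padded, range(2, n + 2), axis=ax)
        lo = np.take(padded, range(0, n), axis=ax)
        out += hi - 2.0 * values + lo
    return out


class TestGradientDivergence:
    def test_constant_image_zero_gradient(self):
        assert np.all(gradient4d(np.full((3, 4, 2, 5), 7.0)) == 0)

    def test_linear_ramp(self):
        shape = (5, 3, 3, 4)
        x = np.broadcast_to(np.arange(5.0)[:, None, None, None], shape).copy()
        g = gradient4d(x)
        assert np.all(g[:-1, ..., 0] == 1.0)
        assert np.all(g[-1, ..., 0] == 0.0)  # trailing Neumann boundary
        assert np.all(g[..., 1:] == 0.0)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(4, 4, 4, 5))
        np.testing.assert_allclose(gradient4d(x), loop_gradient(x), atol=1e-14)
        sp = (0.5, 2.0, 1.0, 0.25)
        np.testing.assert_allclose(gradient4d(x, sp), loop_gradient(x, sp), atol=1e-13)

    def test_zero_flux_zero_divergence(self):
        assert np.all(divergence4d(np.zeros((3, 3, 3, 3, 4))) == 0)

    def test_div_grad_is_neumann_laplacian(self, rng):
        x = rng.normal(size=(5, 4, 3, 6))
        np.testing.assert_allclose(
            divergence4d(gradient4d(x)), neumann_laplacian(x), atol=1e-12
        )

    def test_div_grad_exact_on_integers(self, rng):
        x = rng.integers(-10, 10, size=(4, 4, 4, 4)).astype(float)
        lap = divergence4d(gradient4d(x))
        np.testing.assert_array_equal(lap, neumann_laplacian(x))
        assert np.all(lap == np.round(lap))  # integer stencil output

    def test_neg_divergence_adjoint_of_gradient(self, rng):
        # <grad I, P> == -<I, div P> over 50 random pairs
        for _ in range(50):
            I = rng.normal(size=(4, 3, 5, 4))
            P = rng.normal(size=(4, 3, 5, 4, 4))
            lhs = np.sum(gradient4d(I) * P)
            rhs = -np.sum(I * divergence4d(P))
            assert abs(lhs - rhs) <= 1e-10

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            gradient4d(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            divergence4d(np.zeros((3, 3, 3, 3, 3)))


class TestStructureTensor:
    def test_zero_gradient_gives_zero_tensor(self):
        grad = np.zeros((3, 3, 3, 3, 4))
        st = structure_tensor(grad, sigma_g=1.0)
        assert np.all(st.components == 0)

    def test_single_voxel_hand_value(self):
        # gradient (2,0,0,0): outer product / norm = diag(4,0,0,0)/2
        grad = np.zeros((1, 1, 1, 1, 4))
        grad[0, 0, 0, 0] = [2.0, 0.0, 0.0, 0.0]
        st = structure_tensor(grad, sigma_g=0.0, epsilon=0.0)
        expected = np.zeros((4, 4))
        expected[0, 0] = 2.0
        np.testing.assert_allclose(st.to_matrices()[0, 0, 0, 0], expected, atol=1e-14)

    def test_sigma_zero_limit_consistency(self, rng):
        grad = rng.normal(size=(4, 4, 4, 4, 4))
        hard = structure_tensor(grad, sigma_g=0.0)
        soft = structure_tensor(grad, sigma_g=1e-4)
        np.testing.assert_allclose(hard.components, soft.components, atol=1e-6)

    def test_squared_norm_gives_unit_trace(self, rng):
        grad = rng.normal(size=(3, 3, 3, 3, 4)) * 10
        st = structure_tensor(grad, sigma_g=0.0, normalization="squared")
        trace = st.components[..., [0, 4, 7, 9]].sum(axis=-1)
        np.testing.assert_allclose(trace, 1.0, atol=1e-6)

    def test_axis_permutation_equivariance(self, rng):
        # permuting image axes permutes the unsmoothed tensor consistently
        x = rng.normal(size=(4, 4, 4, 4))
        perm = (2, 0, 3, 1)
        g1 = gradient4d(x)
        g2 = gradient4d(np.transpose(x, perm))
        m1 = structure_tensor(g1, sigma_g=0.0).to_matrices()
        m2 = structure_tensor(g2, sigma_g=0.0).to_matrices()
        m1_perm = np.transpose(m1, perm + (4, 5))[..., perm, :][..., :, perm]
        np.testing.assert_allclose(m2, m1_perm, atol=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            structure_tensor(np.zeros((2, 2, 2, 2, 4)), sigma_g=-1.0)


class TestEigenSystem:
    def test_diagonal_tensor_sorted(self):
        fld = TensorField4D.from_matrices(np.diag([1.0, 3.0, 2.0, 0.0])[None, None, None, None])
        eigs = eigendecompose(fld)
        np.testing.assert_allclose(eigs.values[0, 0, 0, 0], [3.0, 2.0, 1.0, 0.0], atol=1e-12)
        # eigenvectors are axis-aligned (up to sign)
        Q = np.abs(eigs.vectors[0, 0, 0, 0])
        np.testing.assert_allclose(Q[[1, 2, 0, 3], [0, 1, 2, 3]], 1.0, atol=1e-12)

    def test_identity_tensor_reconstruction(self):
        fld = TensorField4D.from_matrices(np.eye(4)[None, None, None, None])
        eigs = eigendecompose(fld)
        np.testing.assert_allclose(eigs.values, 1.0, atol=1e-12)
        recon = np.einsum("...ik,...k,...jk->...ij", eigs.vectors, eigs.values, eigs.vectors)
        np.testing.assert_allclose(recon[0, 0, 0, 0], np.eye(4), atol=1e-12)

    def test_random_psd_reconstruction(self, rng):
        A = rng.normal(size=(100, 4, 4))
        psd = np.einsum("nij,nkj->nik", A, A)
        fld = TensorField4D.from_matrices(psd.reshape(100, 1, 1, 1, 4, 4))
        eigs = eigendecompose(fld)
        recon = np.einsum("...ik,...k,...jk->...ij", eigs.vectors, eigs.values, eigs.vectors)
        assert np.max(np.abs(recon - fld.to_matrices())) <= 1e-10 * max(1.0, np.abs(psd).max())
        # orthogonality per voxel
        qtq = np.einsum("...ki,...kj->...ij", eigs.vectors, eigs.vectors)
        np.testing.assert_allclose(qtq, np.broadcast_to(np.eye(4), qtq.shape), atol=1e-8)
        assert np.all(np.diff(eigs.values, axis=-1) <= 1e-12)  # descending

    def test_large_negative_eigenvalue_raises(self):
        fld = TensorField4D.from_matrices(np.diag([1.0, 1.0, 1.0, -0.5])[None, None, None, None])
        with pytest.raises(ValueError, match="positive semi-definite"):
            eigendecompose(fld)

    def test_small_negative_clipped(self):
        fld = TensorField4D.from_matrices(np.diag([1.0, 0.5, 0.1, -5e-9])[None, None, None, None])
        eigs = eigendecompose(fld)
        assert np.all(eigs.values >= 0)


class TestRemapAndRebuild:
    def test_zero_leading_eigenvalue_fully_isotropic(self):
        eigs = EigenSystem(vectors=np.eye(4)[None], values=np.zeros((1, 4)))
        lam = remap_eigenvalues(eigs, global_max=1.0)
        np.testing.assert_allclose(lam[0], 1.0)

    def test_unit_ratio_extreme(self):
        # lambda1 == global max, sigma_d = 0.2 -> exp(-12.5)
        eigs = EigenSystem(vectors=np.eye(4)[None], values=np.array([[2.0, 0.5, 0.1, 0.0]]))
        lam = remap_eigenvalues(eigs, global_max=2.0, cfg=RemapConfig(sigma_d=0.2))
        assert lam[0, 0] == pytest.approx(np.exp(-12.5), rel=1e-14)
        np.testing.assert_allclose(lam[0, 1:], 1.0)

    def test_non_leading_always_one(self, rng):
        vals = np.sort(rng.uniform(0, 5, size=(50, 4)), axis=-1)[:, ::-1]
        eigs = EigenSystem(vectors=np.broadcast_to(np.eye(4), (50, 4, 4)).copy(), values=vals)
        lam = remap_eigenvalues(eigs, global_max=float(vals.max()))
        np.testing.assert_allclose(lam[:, 1:], 1.0)
        assert np.all(lam > 0) and np.all(lam <= 1.0)

    def test_remap_strictly_decreasing_in_ratio(self):
        ratios = np.linspace(0, 1, 25)
        eigs = EigenSystem(vectors=np.broadcast_to(np.eye(4), (25, 4, 4)).copy(),
                           values=np.stack([ratios, *([np.zeros(25)] * 3)], axis=-1))
        lam = remap_eigenvalues(eigs, global_max=1.0)
        assert np.all(np.diff(lam[:, 0]) < 0)

    def test_all_ones_rebuilds_identity(self, rng):
        A = rng.normal(size=(10, 4, 4))
        q, _ = np.linalg.qr(A)
        eigs = EigenSystem(vectors=q, values=np.ones((10, 4)))
        fld = rebuild_tensor(eigs, np.ones((10, 4)))
        np.testing.assert_allclose(
            fld.to_matrices(), np.broadcast_to(np.eye(4), (10, 4, 4)), atol=1e-12
        )

    def test_axis_aligned_rebuild(self):
        lam1 = np.exp(-12.5)
        eigs = EigenSystem(vectors=np.eye(4)[None], values=np.array([[1.0, 1.0, 1.0, 1.0]]))
        fld = rebuild_tensor(eigs, np.array([[lam1, 1.0, 1.0, 1.0]]))
        np.testing.assert_allclose(fld.to_matrices()[0], np.diag([lam1, 1, 1, 1]), atol=1e-15)

    def test_spectral_round_trip(self, rng):
        A = rng.normal(size=(2, 2, 2, 2, 4, 4))
        q, _ = np.linalg.qr(A)
        remapped = np.concatenate(
            [rng.uniform(1e-6, 1, size=(2, 2, 2, 2, 1)), np.ones((2, 2, 2, 2, 3))], axis=-1
        )
        fld = rebuild_tensor(EigenSystem(vectors=q, values=np.ones((2, 2, 2, 2, 4))), remapped)
        eigs2 = eigendecompose(fld)
        np.testing.assert_allclose(
            np.sort(eigs2.values, axis=-1), np.sort(remapped, axis=-1), atol=1e-8
        )

    def test_steering_tensor_spd_spectrum_and_trace(self, rng):
        x = rng.normal(size=(6, 6, 6, 8))
        fld, gmax = steering_tensor(x, sigma_g=1.0)
        assert gmax > 0
        eigs = np.linalg.eigvalsh(fld.to_matrices())
        assert np.all(eigs > 0) and np.all(eigs <= 1 + 1e-12)
        trace = fld.components[..., [0, 4, 7, 9]].sum(axis=-1)
        assert np.all(trace > 3.0 - 1e-12) and np.all(trace <= 4.0 + 1e-12)
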