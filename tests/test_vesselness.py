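import numpy as np
import pytest

from corogrow import apply_window, straight_tube_phantom
from corogrow.errors import InputError, ParameterError
from corogrow.vesselness import (
    EigenField,
    ScaleSpaceParams,
    VesselnessParams,
    eigen_decompose,
    gaussian_kernel_value,
    gaussian_smooth,
    hessian_field,
    vesselness_at_scale,
    vesselness_multiscale,
    vesselness_single_scale,
)


def eigenfield_from_triples(triples):
    w = np.asarray(triples, dtype=float)
    vecs = np.broadcast_to(np.eye(3), w.shape[:-1] + (3, 3)).copy()
    return EigenField(eigenvalues=w, eigenvectors=vecs)


class TestGaussianSmoothing:
    def test_constant_volume_preserved(self):
        v = np.full((8, 8, 8), 3.7)
        assert np.allclose(gaussian_smooth(v, 1.5), 3.7)

    def test_kernel_value_at_origin(self):
        assert gaussian_kernel_value(0.0, 1.0) == pytest.approx((2 * np.pi) ** -1.5)

    def test_sampled_kernel_has_unit_mass(self):
        ax = np.arange(-8, 9)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        assert abs(gaussian_kernel_value(r, 1.0).sum() - 1.0) < 1e-3

    def test_invalid_scale(self):
        with pytest.raises(ParameterError):
            gaussian_smooth(np.zeros((4, 4, 4)), 0.0)


class TestHessian:
    def test_quadratic_ramp_second_derivative(self):
        zz, yy, xx = np.meshgrid(*map(np.arange, (16, 16, 16)), indexing="ij")
        h = hessian_field(
            (xx**2).astype(float), 1.0, ScaleSpaceParams(gamma_normalize=False)
        )
        interior = (slice(5, 11),) * 3
        assert np.allclose(h.ixx[interior], 2.0, atol=0.02)
        for comp in (h.iyy, h.izz, h.ixy, h.ixz, h.iyz):
            assert np.allclose(comp[interior], 0.0, atol=0.02)

    def test_constant_volume_zero_hessian(self):
        # truncated discrete derivative kernels leave ~1e-4 residuals
        h = hessian_field(np.full((8, 8, 8), 5.0), 1.0)
        for comp in (h.ixx, h.ixy, h.ixz, h.iyy, h.iyz, h.izz):
            assert np.allclose(comp, 0.0, atol=1e-3)

    def test_gamma_normalization_scales_by_alpha_squared(self):
        zz, yy, xx = np.meshgrid(*map(np.arange, (12, 12, 12)), indexing="ij")
        v = (xx**2).astype(float)
        plain = hessian_field(v, 2.0, ScaleSpaceParams(gamma_normalize=False))
        gamma = hessian_field(v, 2.0, ScaleSpaceParams(gamma_normalize=True))
        assert np.allclose(gamma.ixx, 4.0 * plain.ixx)

    def test_too_small_volume_rejected(self):
        with pytest.raises(InputError):
            hessian_field(np.zeros((2, 2, 2)), 1.0)

    def test_tube_axis_eigenvector_alignment(self, tube, tube_enhanced):
        """On a tube along x, the smallest-|eigenvalue| eigenvector is axial."""
        e = eigen_decompose(hessian_field(tube_enhanced, 2.0))
        mid = tuple(np.array(tube.volume.shape) // 2)
        axial = e.eigenvectors[mid][:, 0]  # (z, y, x) components
        angle = np.degrees(np.arccos(min(1.0, abs(axial[2]))))
        assert angle < 10.0


class TestEigenDecomposition:
    def test_diagonal_matrix_absolute_ordering(self):
        from corogrow.vesselness import HessianField

        zeros = np.zeros((1, 1, 1))
        h = HessianField(
            alpha=1.0,
            izz=zeros, iyy=np.full((1, 1, 1), -5.0), ixx=np.full((1, 1, 1), -5.0),
            ixy=zeros, ixz=zeros, iyz=zeros,
        )
        e = eigen_decompose(h)
        assert np.allclose(e.eigenvalues[0, 0, 0], [0.0, -5.0, -5.0])

    def test_zero_matrix(self):
        from corogrow.vesselness import HessianField

        z = np.zeros((2, 2, 2))
        e = eigen_decompose(HessianField(1.0, z, z, z, z, z, z))
        assert np.allclose(e.eigenvalues, 0.0)

    def test_reconstruction_on_random_symmetric(self, rng):
        """V diag(w) V^T reproduces H to 1e-8 on 100 random symmetric matrices."""
        from corogrow.vesselness import HessianField

        a = rng.normal(size=(100, 1, 1, 3, 3))
        sym = (a + a.swapaxes(-1, -2)) / 2
        h = HessianField(
            alpha=1.0,
            izz=sym[..., 0, 0], iyy=sym[..., 1, 1], ixx=sym[..., 2, 2],
            iyz=sym[..., 0, 1], ixz=sym[..., 0, 2], ixy=sym[..., 1, 2],
        )
        e = eigen_decompose(h)
        rec = np.einsum(
            "...ij,...j,...kj->...ik", e.eigenvectors, e.eigenvalues, e.eigenvectors
        )
        assert np.abs(rec - h.as_matrices()).max() < 1e-8
        # ordering and orthonormality
        assert np.all(np.diff(np.abs(e.eigenvalues), axis=-1) >= -1e-12)
        gram = np.einsum("...ji,...jk->...ik", e.eigenvectors, e.eigenvectors)
        assert np.abs(gram - np.eye(3)).max() < 1e-6

    def test_non_finite_rejected(self):
        from corogrow.vesselness import HessianField

        z = np.zeros((1, 1, 1))
        bad = np.full((1, 1, 1), np.nan)
        with pytest.raises(InputError):
            eigen_decompose(HessianField(1.0, bad, z, z, z, z, z))


class TestVesselnessFunctional:
    def test_positive_eigenvalues_give_zero(self):
        v = vesselness_single_scale(eigenfield_from_triples([[1.0, 2.0, 3.0]]))
        assert v[0] == 0.0

    def test_ideal_tube_closed_form(self):
        """(0,-5,-5) with eps=phi=0.5, structure scale 5 -> (1-e^-2)(1-e^-1)."""
        params = VesselnessParams(eps=0.5, phi=0.5, structure_scale=5.0)
        v = vesselness_single_scale(eigenfield_from_triples([[0.0, -5.0, -5.0]]), params)
        expected = (1 - np.exp(-2)) * (1 - np.exp(-1))
        assert v[0] == pytest.approx(expected, abs=1e-9)
        assert v[0] == pytest.approx(0.5466, abs=1e-4)

    def test_all_zero_eigenvalues_give_zero(self):
        v = vesselness_single_scale(eigenfield_from_triples([[0.0, 0.0, 0.0]]))
        assert v[0] == 0.0

    def test_tube_beats_plate_and_blob(self):
        """Shape discrimination on ideal eigenvalue triples."""
        params = VesselnessParams(eps=0.5, phi=0.5, structure_scale=5.0)
        c = 5.0
        tube, plate, blob = vesselness_single_scale(
            eigenfield_from_triples([[0, -c, -c], [0, 0, -c], [-c, -c, -c]]), params
        )
        assert tube > plate and tube > blob

    def test_dark_vessel_mode_flips_sign_test(self):
        params = VesselnessParams(structure_scale=5.0, bright_vessels=False)
        v = vesselness_single_scale(eigenfield_from_triples([[0.0, 5.0, 5.0]]), params)
        assert v[0] > 0.0
        v2 = vesselness_single_scale(eigenfield_from_triples([[0.0, -5.0, -5.0]]), params)
        assert v2[0] == 0.0

    def test_range_on_random_eigenvalues(self, rng):
        triples = rng.normal(scale=10, size=(500, 3))
        order = np.argsort(np.abs(triples), axis=-1)
        triples = np.take_along_axis(triples, order, axis=-1)
        for ss in (0.5, 5.0, None):
            v = vesselness_single_scale(
                eigenfield_from_triples(triples), VesselnessParams(structure_scale=ss)
            )
            assert v.min() >= 0.0 and v.max() <= 1.0


class TestMultiscale:
    def test_single_scale_list_reduces_to_single_scale(self, tube_enhanced):
        sp = ScaleSpaceParams(scales=(1.0,))
        fused = vesselness_multiscale(tube_enhanced, sp)
        single = vesselness_at_scale(tube_enhanced, 1.0, sp)
        assert np.array_equal(fused, single)

    def test_fused_dominates_each_scale(self, tube_enhanced):
        sp = ScaleSpaceParams(scales=(0.5, 1.0, 2.0))
        fused = vesselness_multiscale(tube_enhanced, sp)
        for a in sp.scales:
            assert np.all(fused >= vesselness_at_scale(tube_enhanced, a, sp) - 1e-12)

    def test_thin_and_thick_tubes_both_caught_by_fusion(self):
        """Fusion preserves vessels of different radii that single scales miss."""
        thin = straight_tube_phantom(shape=(32, 32, 40), radius=1.0, noise_sigma=0.0)
        thick = straight_tube_phantom(shape=(32, 32, 40), radius=3.0, noise_sigma=0.0)
        sp = ScaleSpaceParams(scales=(0.5, 1.0, 2.0, 3.0))
        for s in (thin, thick):
            enh = apply_window(s.volume)
            fused = vesselness_multiscale(enh, sp)
            mid = tuple(np.array(s.volume.shape) // 2)
            assert fused[mid] > 0.2
            worst = min(vesselness_at_scale(enh, a, sp)[mid] for a in sp.scales)
            assert worst < 0.5 * fused[mid]

    def test_gamma_normalized_argmax_scale_tracks_radius(self):
        """The best-responding scale is the grid scale nearest the tube radius."""
        scales = (0.5, 1.0, 2.0, 3.0)
        for r in (1.0, 2.0, 3.0):
            s = straight_tube_phantom(shape=(32, 32, 40), radius=r, noise_sigma=0.0)
            enh = apply_window(s.volume)
            mid = tuple(np.array(s.volume.shape) // 2)
            responses = [vesselness_at_scale(enh, a)[mid] for a in scales]
            assert scales[int(np.argmax(responses))] == r

    def test_rotation_equivariance_grid_aligned(self):
        s = straight_tube_phantom(shape=(32, 32, 32), radius=2.0, noise_sigma=0.0)
        enh = apply_window(s.volume)
        v = vesselness_multiscale(enh)
        v_rot = vesselness_multiscale(np.rot90(enh, axes=(1, 2)))
        assert np.allclose(np.rot90(v, axes=(1, 2)), v_rot, atol=1e-12)

    def test_invalid_scale_lists_rejected(self):
        with pytest.raises(ParameterError):
            ScaleSpaceParams(scales=()).validate()
        with pytest.raises(ParameterError):
            ScaleSpaceParams(scales=(1.0, 1.0)).validate()
        with pytest.raises(ParameterError):
            ScaleSpaceParams(scales=(-1.0, 2.0)).validate()
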