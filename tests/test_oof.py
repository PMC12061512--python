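"""Gaussian Hessian, symmetric 3x3 eigensystem, multiscale OOF response."""

import numpy as np
import pytest

from octafuse import AngiogramVolume, ValidationError
from octafuse.core import BinaryMask3D
from octafuse.oof import (
    OOFParams,
    apply_oof_capillaries,
    eig_symmetric3,
    gaussian_hessian,
    oof_response,
)


def vol(data, pitch=(1.0, 1.0, 1.0)):
    return AngiogramVolume(data=np.asarray(data, dtype=float), pitch_um=pitch,
                           provenance="fused")


def cylinder(radius_um, axis=2, shape=(40, 40, 40), pitch=1.0, bright=True):
    """Binary cylinder along the given axis through the volume center."""
    idx = np.indices(shape, dtype=float) + 0.5
    center = [s / 2 for s in shape]
    axes = [a for a in range(3) if a != axis]
    r2 = sum((idx[a] - center[a]) ** 2 for a in axes) * pitch**2
    tube = r2 <= radius_um**2
    data = tube.astype(float) if bright else 1.0 - tube.astype(float)
    return vol(data, pitch=(pitch,) * 3)


def eigvals_oracle(M: np.ndarray) -> np.ndarray:
    """Characteristic-polynomial roots of one symmetric 3x3 matrix."""
    c2 = -np.trace(M)
    c1 = (M[0, 0] * M[1, 1] + M[0, 0] * M[2, 2] + M[1, 1] * M[2, 2]
          - M[0, 1] ** 2 - M[0, 2] ** 2 - M[1, 2] ** 2)
    c0 = -np.linalg.det(M)
    roots = np.roots([1.0, c2, c1, c0])
    return np.sort(roots.real)


class TestGaussianHessian:
    def test_constant_volume_all_zero(self):
        H = gaussian_hessian(vol(np.full((16, 16, 16), 3.0)), r_um=4.0)
        assert np.allclose(H.components, 0.0, atol=1e-10)

    def test_quadratic_second_derivative(self):
        """f = x^2 has d2f/dx2 = 2 and vanishing cross terms away from the
        boundary (Gaussian smoothing preserves second moments of quadratics)."""
        shape = (24, 24, 24)
        x = np.indices(shape, dtype=float)[1]
        H = gaussian_hessian(vol(x**2), r_um=3.0)
        interior = (slice(8, 16),) * 3
        zz, xx, yy, zx, zy, xy = H.components
        assert np.allclose(xx[interior], 2.0, atol=1e-6)
        for comp in (zz, yy, zx, zy, xy):
            assert np.allclose(comp[interior], 0.0, atol=1e-6)

    def test_mirror_symmetry_antisymmetrizes_cross_term(self):
        """For input mirror-symmetric in x, the mixed derivative d2f/dxdy
        is antisymmetric in x."""
        rng = np.random.default_rng(0)
        half = rng.random((16, 8, 16))
        data = np.concatenate([half, half[:, ::-1, :]], axis=1)
        H = gaussian_hessian(vol(data), r_um=3.0)
        xy = H.components[5]  # d2/dxdy
        assert np.allclose(xy, -xy[:, ::-1, :], atol=1e-9)

    def test_under_resolved_scale_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_hessian(vol(np.zeros((8, 8, 8)), pitch=(4, 4, 4)), r_um=3.0)


class TestEigSymmetric3:
    def _field(self, comps):
        from octafuse.oof import HessianField
        return HessianField(components=np.asarray(comps, dtype=float).reshape(6, 1, 1, 1),
                            scale_um=1.0)

    def test_diagonal_matrix(self):
        lam1, lam2, lam3, V1 = eig_symmetric3(self._field([-3, -1, 2, 0, 0, 0]))
        assert (lam1[0, 0, 0], lam2[0, 0, 0], lam3[0, 0, 0]) == (-3, -1, 2)
        assert np.allclose(np.abs(V1[0, 0, 0]), [1, 0, 0])

    def test_zero_matrix(self):
        lam1, lam2, lam3, _ = eig_symmetric3(self._field([0] * 6))
        assert lam1[0, 0, 0] == lam2[0, 0, 0] == lam3[0, 0, 0] == 0

    def test_random_matrices_match_polynomial_oracle(self):
        """Eigenvalues agree with characteristic-polynomial roots and the
        (lam1, V1) pair satisfies H V1 = lam1 V1, both to 1e-9."""
        from octafuse.oof import HessianField
        rng = np.random.default_rng(77)
        n = 10_000
        comps = rng.standard_normal((6, n, 1, 1))
        H = HessianField(components=comps, scale_um=1.0)
        lam1, lam2, lam3, V1 = eig_symmetric3(H)
        lams = np.stack([lam1, lam2, lam3], axis=-1)[:, 0, 0]
        v1 = V1[:, 0, 0]
        for i in range(n):
            M = np.array([[comps[0, i, 0, 0], comps[3, i, 0, 0], comps[4, i, 0, 0]],
                          [comps[3, i, 0, 0], comps[1, i, 0, 0], comps[5, i, 0, 0]],
                          [comps[4, i, 0, 0], comps[5, i, 0, 0], comps[2, i, 0, 0]]])
            assert np.allclose(lams[i], eigvals_oracle(M), atol=1e-9)
            assert np.linalg.norm(M @ v1[i] - lams[i][0] * v1[i]) <= 1e-9
            assert np.linalg.norm(v1[i]) == pytest.approx(1.0, abs=1e-12)


class TestOOFResponse:
    SCALES = OOFParams(scales_um=(3.0, 4.5, 6.0, 9.0, 12.0))

    def test_constant_volume_zero_response(self):
        out = oof_response(vol(np.full((20, 20, 20), 5.0)), self.SCALES)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(1)
        out = oof_response(vol(rng.random((20, 20, 20))), self.SCALES)
        assert (out.data >= 0).all()

    def test_bright_cylinder_scale_selection(self):
        """A radius-6 um bright tube responds on-axis with argmax scale
        within one scale step of the radius, and near-zero far background."""
        c = cylinder(6.0)
        out, argmax = oof_response(c, self.SCALES, return_scale_argmax=True)
        center = (20, 20)
        axis_resp = out.data[center[0], center[1], :]
        assert (axis_resp > 0).all()
        axis_scales = argmax[center[0], center[1], :]
        assert set(np.unique(axis_scales)) <= {4.5, 6.0, 9.0}
        corner = out.data[2, 2, :]
        assert corner.max() < 0.05 * axis_resp.max()

    def test_dark_cylinder_no_axial_response(self):
        bright = oof_response(cylinder(6.0), self.SCALES).data[20, 20, :]
        dark = oof_response(cylinder(6.0, bright=False), self.SCALES).data[20, 20, :]
        assert dark.max() < 0.01 * bright.max()

    def test_rotation_consistency(self):
        """Permuting the volume axes permutes the response (within 5%)."""
        c = cylinder(6.0)
        out_z = oof_response(vol(np.transpose(c.data, (2, 0, 1))), self.SCALES).data
        out_y = np.transpose(oof_response(c, self.SCALES).data, (2, 0, 1))
        peak = out_y.max()
        assert np.abs(out_z - out_y).max() <= 0.05 * peak

    def test_scale_tracks_radius(self):
        """Thin and thick tubes in one volume select different scales, each
        within one scale step of its radius."""
        shape = (40, 80, 40)
        idx = np.indices(shape, dtype=float) + 0.5
        thin = ((idx[0] - 20) ** 2 + (idx[1] - 20) ** 2) <= 4.0**2
        thick = ((idx[0] - 20) ** 2 + (idx[1] - 60) ** 2) <= 8.0**2
        v = vol((thin | thick).astype(float))
        _, argmax = oof_response(v, self.SCALES, return_scale_argmax=True)
        thin_scales = argmax[20, 20, 10:30]
        thick_scales = argmax[20, 60, 10:30]
        assert np.median(thin_scales) in (3.0, 4.5, 6.0)
        assert np.median(thick_scales) in (6.0, 9.0, 12.0)
        assert np.median(thick_scales) > np.median(thin_scales)


class TestApplyCapillaries:
    def test_mask_all_true_passes_through(self):
        rng = np.random.default_rng(2)
        fused = vol(rng.random((16, 16, 16)))
        full = BinaryMask3D(data=np.ones((16, 16, 16), dtype=bool))
        out = apply_oof_capillaries(fused, full, OOFParams(scales_um=(3.0,)))
        assert np.array_equal(out.data, fused.data)

    def test_mask_all_false_is_rescaled_response(self):
        rng = np.random.default_rng(3)
        fused = vol(rng.random((16, 16, 16)))
        empty = BinaryMask3D(data=np.zeros((16, 16, 16), dtype=bool))
        params = OOFParams(scales_um=(3.0,))
        out = apply_oof_capillaries(fused, empty, params)
        resp = oof_response(fused, params)
        scale = (np.percentile(fused.data, 99) / np.percentile(resp.data, 99))
        assert np.allclose(out.data, scale * resp.data, rtol=1e-9)

    def test_inside_mask_bit_identical_on_phantom(self, small_run):
        m = small_run.mask3d.data
        assert np.array_equal(small_run.oof.data[m], small_run.fused.data[m])
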