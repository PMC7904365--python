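import numpy as np
import pytest
from skimage.filters import threshold_otsu

from oct_edema.enhance import (
    GaussianKernelSpec,
    RetinexConfig,
    StructureTransferConfig,
    enhance,
    gaussian_kernel,
    gf_smooth,
    guidance_field,
    retinex_ssr,
    structure_transfer,
    surround_kernel,
)
from oct_edema.phantom import default_spec, generate_phantom


class TestGaussianKernel:
    @pytest.mark.parametrize("sigma,size", [(0.5, 3), (1.0, 5), (2.5, 7)])
    def test_unit_sum_symmetry_and_central_maximum(self, sigma, size):
        k = gaussian_kernel(GaussianKernelSpec(sigma=sigma, size=size))
        assert abs(k.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(k, k.T)
        np.testing.assert_allclose(k, k[::-1, ::-1])
        assert k[size // 2, size // 2] == k.max()

    def test_center_to_corner_ratio(self):
        # exp(0) / exp(-(2^2+2^2)/2) = e^4, preserved by renormalization
        k = gaussian_kernel(GaussianKernelSpec(sigma=1.0, size=5))
        np.testing.assert_allclose(k[2, 2] / k[0, 0], np.exp(4.0), rtol=1e-12)

    @pytest.mark.parametrize("size", [2, 4, 1])
    def test_even_or_tiny_size_rejected(self, size):
        with pytest.raises(ValueError):
            GaussianKernelSpec(sigma=1.0, size=size)


class TestGfSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 0.37)
        np.testing.assert_allclose(gf_smooth(img), img)

    def test_impulse_response_is_the_kernel(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        out = gf_smooth(img, GaussianKernelSpec(sigma=1.0, size=5))
        np.testing.assert_allclose(out[5:10, 5:10], gaussian_kernel(GaussianKernelSpec(1.0, 5)))

    def test_never_expands_value_range(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.2, 0.9, (32, 32))
        out = gf_smooth(img)
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12

    def test_reduces_speckle_variance_in_band(self):
        pair = generate_phantom(default_spec(seed=1))
        band = pair.retina_mask & ~pair.edema_mask
        out = gf_smooth(pair.image)
        assert out[band].var() < pair.image[band].var()


def _dense_solve(image, vh, vv, lam):
    """Brute-force oracle: assemble the dense system and solve directly."""
    h, w = image.shape
    n = h * w

    def dx_apply(f):
        d = np.zeros_like(f)
        d[:, :-1] = f[:, 1:] - f[:, :-1]
        return d

    def dy_apply(f):
        d = np.zeros_like(f)
        d[:-1, :] = f[1:, :] - f[:-1, :]
        return d

    dx = np.zeros((n, n))
    dy = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        dx[:, j] = dx_apply(e.reshape(h, w)).ravel()
        dy[:, j] = dy_apply(e.reshape(h, w)).ravel()
    a = lam * np.eye(n) + dx.T @ dx + dy.T @ dy
    rhs = lam * image.ravel() + dx.T @ vh.ravel() + dy.T @ vv.ravel()
    return np.linalg.solve(a, rhs).reshape(h, w)


class TestStructureTransfer:
    def test_identity_when_guidance_is_own_gradients(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (12, 17))
        vh = np.zeros_like(img)
        vh[:, :-1] = img[:, 1:] - img[:, :-1]
        vv = np.zeros_like(img)
        vv[:-1, :] = img[1:, :] - img[:-1, :]
        out = structure_transfer(img, (vh, vv), lam=0.3)
        np.testing.assert_allclose(out, img, atol=1e-7)

    def test_large_lambda_returns_input(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 1, (16, 16))
        vh = rng.normal(0, 0.5, img.shape)
        vv = rng.normal(0, 0.5, img.shape)
        out = structure_transfer(img, (vh, vv), lam=1e6)
        assert np.max(np.abs(out - img)) < 1e-3

    @pytest.mark.parametrize("shape", [(5, 5), (8, 8), (7, 11), (16, 16)])
    def test_matches_dense_direct_solve(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        img = rng.uniform(0, 1, shape)
        other = rng.uniform(0, 1, shape)
        vh, vv = guidance_field(other, 1.0)
        out = structure_transfer(img, (vh, vv), lam=0.1)
        np.testing.assert_allclose(out, _dense_solve(img, vh, vv, 0.1), atol=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structure_transfer(np.zeros((4, 4)), (np.zeros((4, 5)), np.zeros((4, 4))), 0.1)


class TestGuidanceField:
    def test_constant_image_gives_zero_field(self):
        vh, vv = guidance_field(np.full((10, 10), 0.6), 2.0)
        np.testing.assert_allclose(vh, 0.0, atol=1e-12)
        np.testing.assert_allclose(vv, 0.0, atol=1e-12)

    def test_vertical_step_edge_geometry(self):
        img = np.zeros((12, 12))
        img[:, 6:] = 1.0
        vh, vv = guidance_field(img, 0.3)
        np.testing.assert_allclose(vv, 0.0, atol=1e-9)
        assert np.abs(vh[:, 5]).min() > 0.1        # on the step
        assert np.abs(vh[:, [0, 10]]).max() < 1e-6  # far from the step

    def test_transfer_restores_edge_sharpness(self):
        # smoothing blurs a step; structure transfer with the original's
        # guidance recovers a steeper transition
        img = np.zeros((24, 24))
        img[:, 12:] = 1.0
        sm = gf_smooth(img, GaussianKernelSpec(sigma=1.5, size=9))
        vh, vv = guidance_field(img, 0.3)
        out = structure_transfer(sm, (vh, vv), lam=0.05)
        grad_sm = np.abs(np.diff(sm, axis=1)).max()
        grad_out = np.abs(np.diff(out, axis=1)).max()
        assert grad_out > grad_sm


class TestRetinexSSR:
    def test_constant_image_maps_to_zero_field(self):
        img = np.full((20, 20), 0.42)
        r = retinex_ssr(img, RetinexConfig(c=8.0, rescale=False))
        np.testing.assert_allclose(r, 0.0, atol=1e-9)

    @pytest.mark.parametrize("c", [1.0, 15.0, 100.0])
    def test_surround_kernel_unit_sum(self, c):
        assert abs(surround_kernel(c).sum() - 1.0) < 1e-12

    def test_two_level_image_sign_near_boundary(self):
        img = np.full((16, 16), 0.2)
        img[:, 8:] = 0.8
        r = retinex_ssr(img, RetinexConfig(c=4.0, rescale=False))
        assert np.all(r[:, 8] > 0)   # bright side of the edge
        assert np.all(r[:, 7] < 0)   # dark side of the edge

    def test_invalid_surround_rejected(self):
        with pytest.raises(ValueError):
            RetinexConfig(c=0.0)

    def test_rescaled_output_in_unit_interval(self):
        pair = generate_phantom(default_spec(seed=0))
        r = retinex_ssr(pair.image, RetinexConfig(c=100.0, rescale=True))
        assert r.min() >= 0.0 and r.max() <= 1.0
        assert np.all(np.isfinite(r))


class TestEnhancePipeline:
    def test_clean_phantom_thresholds_to_retina(self, phantom_pair):
        from scipy import ndimage

        out = enhance(phantom_pair.clean)
        mask = ndimage.binary_fill_holes(out > threshold_otsu(out))
        truth = phantom_pair.retina_mask
        d = 2 * np.sum(mask & truth) / (mask.sum() + truth.sum())
        assert d >= 0.98

    def test_improves_cnr_and_enl_on_speckled_phantom(self, phantom_pair):
        from oct_edema.metrics import cnr, enl
        from oct_edema.pipeline import truth_roi_set

        rois = truth_roi_set(phantom_pair.retina_mask, phantom_pair.edema_mask)
        out = enhance(phantom_pair.image)
        assert cnr(out, rois) > cnr(phantom_pair.image, rois)
        assert enl(out, rois) > enl(phantom_pair.image, rois)

    def test_deterministic(self, phantom_pair):
        a = enhance(phantom_pair.image)
        b = enhance(phantom_pair.image)
        np.testing.assert_array_equal(a, b)

    def test_output_finite_and_in_unit_interval(self, phantom_pair):
        out = enhance(phantom_pair.image)
        assert np.all(np.isfinite(out))
        assert out.min() >= 0.0 and out.max() <= 1.0
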