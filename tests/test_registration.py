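import numpy as np
import pytest
from scipy import ndimage

import rpemosaic as rm
from rpemosaic.errors import DegenerateGeometryError, ParameterError, ScalingError


def umeyama_oracle(src: np.ndarray, dst: np.ndarray):
    """Independent closed-form similarity fit (textbook Umeyama solution)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    var_s = (sc**2).sum() / len(src)
    scale = np.trace(np.diag(S) @ D) / var_s
    t = mu_d - scale * R @ mu_s
    return scale, np.arctan2(R[1, 0], R[0, 0]), t


class TestPixelSize:
    def test_reference_eye_gives_c(self):
        model = rm.ScalingModel(a=0.02, b=0.5, c=0.7)
        assert rm.pixel_size(0.0, 23.5, model) == 0.7

    def test_linearity_in_refraction(self):
        model = rm.ScalingModel(a=0.02, b=0.5, c=0.7)
        for al in (23.0, 23.5, 25.0):
            diff = rm.pixel_size(1.0, al, model) - rm.pixel_size(0.0, al, model)
            assert diff == pytest.approx(0.02)

    def test_hand_computed_value(self):
        model = rm.ScalingModel(a=0.02, b=0.5, c=0.7)
        assert rm.pixel_size(-2.0, 24.5, model) == pytest.approx(1.16)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ParameterError):
            rm.pixel_size(0.0, 19.0)
        with pytest.raises(ParameterError):
            rm.pixel_size(11.0, 23.5)

    def test_nonpositive_result_is_scaling_error(self):
        model = rm.ScalingModel(a=1.0, b=0.0, c=0.5)
        with pytest.raises(ScalingError):
            rm.pixel_size(-9.0, 23.5, model)


class TestEstimateSimilarity:
    def test_identity(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, (6, 2))
        est = rm.estimate_similarity(pts, pts)
        assert est.scale == pytest.approx(1.0, abs=1e-12)
        assert est.rotation == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(est.translation, 0.0, atol=1e-9)

    def test_known_transform_recovered(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 100, (6, 2))
        true = rm.SimilarityTransform(scale=1.8, rotation=0.3, translation=(5.0, -7.0))
        est = rm.estimate_similarity(src, true.apply(src))
        assert abs(est.scale - 1.8) < 1e-6
        assert abs(est.rotation - 0.3) < 1e-6
        assert np.abs(np.array(est.translation) - (5.0, -7.0)).max() < 1e-6

    def test_matches_closed_form_oracle_under_noise(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 100, (10, 2))
        dst = rm.SimilarityTransform(0.8, -0.5, (3.0, 4.0)).apply(src) + rng.normal(0, 2.0, (10, 2))
        est = rm.estimate_similarity(src, dst)
        scale_o, rot_o, t_o = umeyama_oracle(src, dst)
        assert est.scale == pytest.approx(scale_o, abs=1e-9)
        assert est.rotation == pytest.approx(rot_o, abs=1e-9)
        assert np.allclose(est.translation, t_o, atol=1e-9)

    def test_fewer_than_four_landmarks_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ParameterError):
            rm.estimate_similarity(pts, pts)

    def test_collinear_landmarks_rejected(self):
        src = np.column_stack([np.arange(5.0), np.arange(5.0) * 0.001])
        with pytest.raises(DegenerateGeometryError):
            rm.estimate_similarity(src, src)

    def test_inverse_composition_is_identity(self):
        t = rm.SimilarityTransform(scale=1.7, rotation=0.9, translation=(-3.0, 11.0))
        ident = t.compose(t.inverse())
        assert abs(ident.scale - 1.0) < 1e-9
        assert abs(ident.rotation) < 1e-9
        assert np.abs(ident.translation).max() < 1e-9

    def test_transform_group_property(self):
        """Estimating through two chained transforms equals their product."""
        rng = np.random.default_rng(4)
        src = rng.uniform(0, 100, (8, 2))
        t1 = rm.SimilarityTransform(1.3, 0.2, (2.0, -1.0))
        t2 = rm.SimilarityTransform(0.7, -0.4, (-5.0, 3.0))
        mid = t1.apply(src)
        est1 = rm.estimate_similarity(src, mid)
        est2 = rm.estimate_similarity(mid, t2.apply(mid))
        prod = est2.compose(est1)
        expected = t2.compose(t1)
        assert abs(prod.scale - expected.scale) < 1e-6
        assert abs(prod.rotation - expected.rotation) < 1e-6
        assert np.abs(np.array(prod.translation) - expected.translation).max() < 1e-6

    def test_residual_rms_follows_dof_formula(self):
        """Sum of squared residuals ~ sigma^2 (2n - 4): 4 fitted dof over 2n
        noisy coordinates, so per-landmark distance RMS approaches
        sigma*sqrt(2) from below as n grows; parameter error, by contrast,
        shrinks with n."""
        rng = np.random.default_rng(5)
        sigma = 1.0
        rms_by_n, param_err_by_n = [], []
        for n in (4, 8, 16, 64):
            rms_vals, perr = [], []
            while len(rms_vals) < 300:
                src = rng.uniform(0, 100, (n, 2))
                dst = src + rng.normal(0, sigma, (n, 2))
                try:
                    est = rm.estimate_similarity(src, dst)
                except DegenerateGeometryError:  # rare near-collinear draw
                    continue
                rms_vals.append(est.residual_rms)
                perr.append(abs(est.scale - 1.0))
            rms_by_n.append(np.mean(rms_vals))
            param_err_by_n.append(np.mean(perr))
        for n, rms in zip((4, 8, 16, 64), rms_by_n):
            assert rms == pytest.approx(sigma * np.sqrt(2.0) * np.sqrt(1.0 - 2.0 / n), rel=0.08)
        assert rms_by_n[0] < rms_by_n[-1]  # residual RMS grows toward sigma
        assert param_err_by_n[0] > param_err_by_n[-1]  # parameter error shrinks


class TestWarpMontage:
    def test_identity_reproduces_input(self, rendered):
        img, _ = rendered
        res = rm.warp_montage(img, rm.SimilarityTransform(1.0, 0.0, (0.0, 0.0)), target_pixel_size=img.pixel_size)
        np.testing.assert_allclose(res.low_res.data, img.data, atol=1e-12)
        assert res.low_mask.all()

    def test_scale_two_quadruples_footprint(self, rendered):
        img, _ = rendered
        t = rm.SimilarityTransform(2.0, 0.0, (0.0, 0.0))
        res = rm.warp_montage(img, t, target_pixel_size=img.pixel_size)
        area_in = img.data.size
        assert res.low_mask.sum() == pytest.approx(4 * area_in, rel=0.02)

    def test_round_trip_loss_is_small(self, rendered):
        img, _ = rendered
        smooth = rm.MosaicImage(ndimage.gaussian_filter(img.data, 3.0), img.pixel_size)
        t = rm.SimilarityTransform(1.2, 0.25, (10.0, 5.0))
        fwd = rm.warp_montage(smooth, t, target_pixel_size=1.0)
        back = rm.warp_montage(fwd.low_res, t.inverse(), target_pixel_size=1.0,
                               target_shape=smooth.data.shape)
        diff = np.abs(back.low_res.data - smooth.data)[back.low_mask]
        assert diff.mean() < 0.02 * (smooth.data.max() - smooth.data.min())

    def test_blob_intensity_conserved(self):
        """Total flux of a compact bright blob survives warping within 5%."""
        img = np.zeros((120, 120))
        yy, xx = np.mgrid[0:120, 0:120]
        img += np.exp(-(((xx - 60) ** 2 + (yy - 60) ** 2) / (2 * 6.0**2)))
        m = rm.MosaicImage(img, 1.0)
        t = rm.SimilarityTransform(1.0, 0.4, (8.0, -3.0))
        res = rm.warp_montage(m, t, target_pixel_size=1.0)
        assert res.low_res.data.sum() == pytest.approx(img.sum(), rel=0.05)


class TestStitchTranslation:
    def test_known_shifts_recovered(self, rendered):
        img, _ = rendered
        big = img.data
        tiles = [big[0:128, 0:128], big[20:148, 100:228], big[90:218, 10:138]]
        nominal = [(0, 0), (18, 103), (92, 8)]  # nominal layout is a few px off
        montage = rm.stitch_translation(tiles, nominal)
        np.testing.assert_allclose(montage.offsets, [(0, 0), (20, 100), (90, 10)], atol=1.0)

    def test_single_image_passthrough(self, rendered):
        img, _ = rendered
        montage = rm.stitch_translation([img.data], [(0, 0)])
        np.testing.assert_array_equal(montage.image, img.data)

    def test_disjoint_tiles_warn_and_use_nominal(self, rendered):
        img, _ = rendered
        tiles = [img.data[0:64, 0:64], img.data[128:192, 128:192]]
        with pytest.warns(UserWarning, match="no usable overlap"):
            montage = rm.stitch_translation(tiles, [(0, 0), (200, 200)])
        assert montage.offsets[1] == (200.0, 200.0)
        assert montage.refined == [True, False]
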