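"""CAM method oracles and contracts.

The GAP+linear toy architecture admits the classic CAM weight projection as
an analytic oracle; piecewise-linear toy nets admit finite-difference
derivative oracles.  Contract tests (normalisation, probability weights,
threshold nesting) run against a briefly trained classifier.
"""

import numpy as np
import pytest

from camagree import cam
from camagree.cam import (
    binarize,
    compute_cam,
    faster_score_cam,
    grad_cam,
    grad_cam_pp,
    gradcam_pp_alpha,
    layer_cam,
    layer_cam_prenorm,
    normalize_heatmap,
    score_cam,
    score_cam_weights,
    top_variance_channels,
)
from camagree.exceptions import DomainError

from conftest import (exp_score_gradient, make_gap_linear_model,
                      make_random_small_net)


def _toy_weights(rng, k=3, positive_class1=True):
    conv_w = rng.normal(size=(k, 1, 3, 3))
    dense_w = rng.normal(size=(k, 2))
    if positive_class1:
        dense_w[:, 1] = np.abs(dense_w[:, 1]) + 0.1
    return conv_w, dense_w


class TestGradCam:
    def test_matches_classic_cam_projection_on_gap_linear_net(self, rng):
        conv_w, dense_w = _toy_weights(rng)
        model = make_gap_linear_model(conv_w, dense_w)
        img = rng.uniform(size=(12, 12))
        heat = grad_cam(model, img, "conv1", class_index=1)
        a = model.activations(img, "conv1")
        classic = np.maximum((a * dense_w[:, 1]).sum(axis=-1), 0.0)
        np.testing.assert_allclose(heat.values, normalize_heatmap(classic),
                                   atol=1e-6)

    def test_single_channel_constant_gradient_gives_clipped_activation(self, rng):
        conv_w, dense_w = _toy_weights(rng, k=1)
        model = make_gap_linear_model(conv_w, dense_w)
        img = rng.uniform(size=(10, 10))
        heat = grad_cam(model, img, "conv1", class_index=1)
        a1 = model.activations(img, "conv1")[:, :, 0]
        np.testing.assert_allclose(heat.values,
                                   normalize_heatmap(np.maximum(a1, 0.0)),
                                   atol=1e-10)

    def test_zero_gradient_gives_all_zero_heatmap(self, rng):
        conv_w, dense_w = _toy_weights(rng)
        dense_w[:, 1] = 0.0  # class-1 score ignores the features
        model = make_gap_linear_model(conv_w, dense_w)
        heat = grad_cam(model, rng.uniform(size=(10, 10)), "conv1", class_index=1)
        assert not heat.values.any()


class TestGradCamPP:
    def test_reduces_to_grad_cam_for_constant_positive_gradients(self, rng):
        conv_w, dense_w = _toy_weights(rng)
        model = make_gap_linear_model(conv_w, dense_w)
        img = rng.uniform(size=(12, 12))
        h_pp = grad_cam_pp(model, img, "conv1", class_index=1)
        h_gc = grad_cam(model, img, "conv1", class_index=1)
        np.testing.assert_allclose(h_pp.values, h_gc.values, atol=1e-6)

    def test_alpha_uniform_for_constant_gradients(self, rng):
        conv_w, dense_w = _toy_weights(rng)
        model = make_gap_linear_model(conv_w, dense_w)
        img = rng.uniform(size=(8, 8))
        a = model.activations(img, "conv1")
        g = model.class_gradient(img, "conv1", class_index=1)
        alpha = gradcam_pp_alpha(a, g, normalize=True)
        np.testing.assert_allclose(alpha, np.full_like(alpha, 1.0 / 64), atol=1e-10)

    def test_zero_gradient_gives_all_zero_heatmap(self, rng):
        conv_w, dense_w = _toy_weights(rng)
        dense_w[:, 1] = 0.0
        model = make_gap_linear_model(conv_w, dense_w)
        heat = grad_cam_pp(model, rng.uniform(size=(8, 8)), "conv1", class_index=1)
        assert not heat.values.any()

    def test_alpha_closed_form_matches_derivative_oracle(self, rng):
        """alpha from the closed form vs second/third derivatives of the
        exponentialised class score, obtained by central finite differences
        of the exact backprop gradient (avoids the catastrophic cancellation
        of differencing the score itself)."""
        model = make_random_small_net(1)
        img = rng.uniform(size=(8, 8))
        layer = "conv2"
        a = model.activations(img, layer)
        g = model.class_gradient(img, layer, class_index=1)
        closed = gradcam_pp_alpha(a, g, normalize=False)

        h = 1e-3
        _, g0 = exp_score_gradient(model, img, layer, a)
        oracle = np.zeros_like(a)
        sum_a = a.sum(axis=(0, 1))
        for idx in np.ndindex(a.shape):
            ap, am = a.copy(), a.copy()
            ap[idx] += h
            am[idx] -= h
            _, gp = exp_score_gradient(model, img, layer, ap)
            _, gm = exp_score_gradient(model, img, layer, am)
            d2 = (gp[idx] - gm[idx]) / (2 * h)
            d3 = (gp[idx] - 2 * g0[idx] + gm[idx]) / h**2
            denom = 2 * d2 + sum_a[idx[2]] * d3
            oracle[idx] = d2 / denom if denom != 0 else 0.0
        assert np.abs(closed - oracle).max() < 1e-5


class TestScoreCam:
    def test_weights_form_probability_vector(self, trained_tiny_model, tiny_dataset):
        img = tiny_dataset[0].damaged_slices[0].image
        w = score_cam_weights(trained_tiny_model, img)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_channel_is_normalized_relu_activation(self, rng):
        conv_w, dense_w = _toy_weights(rng, k=1)
        model = make_gap_linear_model(conv_w, dense_w)
        img = rng.uniform(size=(10, 10))
        heat = score_cam(model, img, "conv1", class_index=1)
        a1 = model.activations(img, "conv1")[:, :, 0]
        np.testing.assert_allclose(heat.values,
                                   normalize_heatmap(np.maximum(a1, 0.0)),
                                   atol=1e-10)

    def test_duplicate_channels_share_weight_and_match_single_channel(self, rng):
        conv_w, dense_w = _toy_weights(rng, k=1)
        dup_conv = np.concatenate([conv_w, conv_w])
        dup_dense = np.vstack([dense_w, dense_w]) / 2.0
        model1 = make_gap_linear_model(conv_w, dense_w)
        model2 = make_gap_linear_model(dup_conv, dup_dense)
        img = rng.uniform(size=(10, 10))
        w = score_cam_weights(model2, img, "conv1")
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(score_cam(model2, img, "conv1").values,
                                   score_cam(model1, img, "conv1").values,
                                   atol=1e-10)

    def test_channel_scaling_leaves_masked_scores_invariant(self, rng):
        # the [0,1] normalisation makes the mask invariant under positive
        # scaling of a channel, so a 10x channel gets the same weight
        conv_w, dense_w = _toy_weights(rng, k=1)
        scaled_conv = np.concatenate([conv_w, conv_w * 10.0])
        model = make_gap_linear_model(scaled_conv, np.vstack([dense_w, dense_w]))
        img = rng.uniform(size=(10, 10))
        w = score_cam_weights(model, img, "conv1")
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)


class TestFasterScoreCam:
    def test_few_channels_identical_to_score_cam(self, rng):
        conv_w, dense_w = _toy_weights(rng, k=3)
        model = make_gap_linear_model(conv_w, dense_w)
        img = rng.uniform(size=(10, 10))
        np.testing.assert_array_equal(
            faster_score_cam(model, img, "conv1", top_n=10).values,
            score_cam(model, img, "conv1").values,
        )

    def test_constant_channels_excluded_by_variance_ranking(self, rng):
        # 12 informative + 8 all-zero channels: the zero channels have zero
        # spatial variance and must not survive the top-10 ranking
        conv_w, dense_w = _toy_weights(rng, k=12)
        conv20 = np.concatenate([conv_w, np.zeros((8, 1, 3, 3))])
        model = make_gap_linear_model(conv20, np.vstack([dense_w,
                                                         rng.normal(size=(8, 2))]))
        img = rng.uniform(size=(10, 10))
        a = model.activations(img, "conv1")
        chans = top_variance_channels(a, 10)
        assert set(chans) <= set(range(12))
        heat = faster_score_cam(model, img, "conv1", top_n=10)
        _, raw = cam._score_cam_core(model, img, "conv1", 1, chans)
        np.testing.assert_allclose(
            heat.values, normalize_heatmap(
                cam._upsample(np.maximum(raw, 0.0), img.shape)), atol=1e-12)

    def test_variance_ties_break_by_lowest_channel_index(self):
        a = np.zeros((4, 4, 5))
        a[..., 1] = a[..., 3] = a[..., 4] = np.arange(16).reshape(4, 4)[..., None][..., 0]
        # channels 1, 3, 4 tie on variance; 0 and 2 are constant
        assert top_variance_channels(a, 2) == [1, 3]


class TestLayerCam:
    def test_constant_gradient_deviation_gives_zero_map_in_paper_mode(self, rng):
        conv_w, dense_w = _toy_weights(rng)
        model = make_gap_linear_model(conv_w, dense_w)
        heat = layer_cam(model, rng.uniform(size=(10, 10)), layers=["conv1"],
                         class_index=1, mode="paper")
        assert not heat.values.any()

    def test_prenorm_maximum_is_tanh_gamma(self, rng):
        conv_w, dense_w = _toy_weights(rng)
        model = make_gap_linear_model(conv_w, dense_w)
        img = rng.uniform(size=(10, 10))
        fused = layer_cam_prenorm(model, img, ["conv1"], class_index=1,
                                  gamma=2.0, mode="classic")
        assert fused.max() == pytest.approx(np.tanh(2.0), abs=1e-12)

    def test_identical_layers_fuse_to_single_layer_map(self, rng):
        conv_w, dense_w = _toy_weights(rng)
        model = make_gap_linear_model(conv_w, dense_w)
        img = rng.uniform(size=(10, 10))
        one = layer_cam(model, img, ["conv1"], mode="classic")
        two = layer_cam(model, img, ["conv1", "conv1"], mode="classic")
        np.testing.assert_array_equal(one.values, two.values)

    def test_multi_layer_default_set_on_trained_model(self, trained_tiny_model,
                                                      tiny_dataset):
        img = tiny_dataset[0].damaged_slices[0].image
        heat = layer_cam(trained_tiny_model, img)
        assert heat.values.shape == img.shape
        assert heat.layer == tuple(trained_tiny_model.stage_last_convs)


class TestBinarize:
    def test_direct_threshold_comparison(self):
        values = np.array([[0.2, 0.5], [0.6, 0.9]])
        np.testing.assert_array_equal(binarize(values, 0.5),
                                      np.array([[0, 1], [1, 1]], dtype=np.uint8))

    def test_all_ones_heatmap(self):
        assert binarize(np.ones((4, 4)), 0.5).all()

    def test_threshold_nesting(self, rng):
        values = rng.uniform(size=(16, 16))
        lo = binarize(values, 0.1)
        hi = binarize(values, 0.9)
        assert not (hi & ~lo).any()

    def test_strict_mode_and_foreground_restriction(self):
        values = np.array([[0.5, 0.9], [0.1, 0.5]])
        assert binarize(values, 0.5, strict=True).sum() == 1
        fg = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        np.testing.assert_array_equal(binarize(values, 0.5, foreground=fg),
                                      np.array([[1, 0], [0, 0]], dtype=np.uint8))

    def test_threshold_domain(self):
        with pytest.raises(DomainError):
            binarize(np.ones((2, 2)), 0.0)
        with pytest.raises(DomainError):
            binarize(np.ones((2, 2)), 1.0)


class TestHeatmapContract:
    @pytest.mark.parametrize("method", sorted(cam.CAM_METHODS))
    def test_range_and_max_on_trained_model(self, method, trained_tiny_model,
                                            tiny_dataset):
        img = tiny_dataset[0].damaged_slices[0].image
        heat = compute_cam(method, trained_tiny_model, img)
        v = heat.values
        assert v.shape == img.shape
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert v.max() == pytest.approx(1.0) or not v.any()

    @pytest.mark.parametrize("method", sorted(cam.CAM_METHODS))
    def test_deterministic_for_fixed_model_and_input(self, method,
                                                     trained_tiny_model,
                                                     tiny_dataset):
        img = tiny_dataset[0].damaged_slices[0].image
        a = compute_cam(method, trained_tiny_model, img).values
        b = compute_cam(method, trained_tiny_model, img).values
        np.testing.assert_array_equal(a, b)
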