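"""Explainers: Grad-CAM against analytic and finite-difference oracles,
superpixel segmentation behavior, LIME against closed-form weighted least
squares, and overlay rendering contracts."""

import numpy as np
import pytest
from matplotlib import colormaps
from skimage.transform import resize

from gallnet import nn
from gallnet.model_core import ArchitectureConfig, ConvStageSpec, Model
from gallnet.xai import (ExplainerConfig, GradCAMResult, LIMEResult, gradcam,
                         lime_explain, render_overlay, segment_superpixels)


def _arch64():
    return ArchitectureConfig(stages=(ConvStageSpec(4),) * 6, input_size=64)


def _toy_model(rng, score_sign=+1.0, dtype=np.float64):
    """Conv(1->1) + ReLU + global-average dense head: the class score is
    score_sign * mean of the single feature map."""
    conv = nn.Conv2D(1, 1, 3, "stage1.conv", rng, dtype=dtype)
    act = nn.ReLU("stage1.relu")
    flat = nn.Flatten("flatten")
    dense = nn.Dense(64 * 64, 1, "logits", rng, dtype=dtype)
    dense.w[...] = score_sign / (64 * 64)
    dense.b[...] = 0.0
    return Model(_arch64(), [conv, act, flat, dense], dtype=dtype)


class TestGradCAM:
    def test_analytic_global_average_model(self, rng):
        """If the score is the global average of one feature map, the
        heatmap is exactly the min-max-normalized activation map."""
        model = _toy_model(rng)
        img = rng.random((64, 64))
        result = gradcam(model, img, 0, "stage1.relu")
        acts = model.forward_collect(img, {"stage1.relu"})[1]["stage1.relu"]
        expected_up = resize(acts[0, :, :, 0], (64, 64), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
        expected = (expected_up - expected_up.min()) \
            / (expected_up.max() - expected_up.min())
        np.testing.assert_allclose(result.heatmap, expected, atol=1e-12)
        assert result.heatmap.max() == pytest.approx(1.0)
        assert (result.raw >= 0).all()

    def test_negative_score_gives_all_zero_heatmap(self, rng):
        model = _toy_model(rng, score_sign=-1.0)
        result = gradcam(model, rng.random((64, 64)), 0, "stage1.relu")
        assert not result.raw.any()
        assert not result.heatmap.any()

    def test_channel_weights_match_finite_differences(self, rng):
        """alpha_k must agree with central finite differences of the class
        score under a uniform perturbation of channel k's activations."""
        conv1 = nn.Conv2D(1, 3, 3, "stage1.conv", rng, dtype=np.float64)
        relu1 = nn.ReLU("stage1.relu")
        conv2 = nn.Conv2D(3, 2, 3, "stage2.conv", rng, dtype=np.float64)
        relu2 = nn.ReLU("stage2.relu")
        flat = nn.Flatten("flatten")
        dense = nn.Dense(16 * 16 * 2, 2, "logits", rng, dtype=np.float64)
        model = Model(_arch64(), [conv1, relu1, conv2, relu2, flat, dense],
                      dtype=np.float64)
        img = rng.random((16, 16))
        x = img[None, :, :, None]
        acts, grads, _ = model.activation_and_gradient(x, 1, "stage1.relu")
        alpha = grads[0].mean(axis=(0, 1))

        downstream = [conv2, relu2, flat, dense]

        def score(a):
            h = a
            for layer in downstream:
                h = layer.forward(h)
            return float(h[0, 1])

        a0 = acts.copy()
        eps = 1e-3
        hw = a0.shape[1] * a0.shape[2]
        for k in range(3):
            hi, lo = a0.copy(), a0.copy()
            hi[..., k] += eps
            lo[..., k] -= eps
            fd = (score(hi) - score(lo)) / (2 * eps) / hw
            assert abs(fd - alpha[k]) <= 1e-3 * max(abs(fd), 1e-9)

    def test_linear_in_activations(self, rng):
        """Scaling the (positive) activations by c > 0 scales the raw map
        by c and leaves the normalized map unchanged."""
        model = _toy_model(rng)
        conv = model.layer("stage1.conv")
        conv.w[...] = np.abs(conv.w)  # keep activations positive
        conv.b[...] = 0.1
        img = rng.random((64, 64)) + 0.5
        r1 = gradcam(model, img, 0, "stage1.relu")
        conv.w[...] *= 3.0
        conv.b[...] *= 3.0
        r3 = gradcam(model, img, 0, "stage1.relu")
        np.testing.assert_allclose(r3.raw, 3.0 * r1.raw, rtol=1e-9)
        np.testing.assert_allclose(r3.heatmap, r1.heatmap, atol=1e-9)

    def test_non_spatial_layer_rejected(self, rng):
        model = _toy_model(rng)
        with pytest.raises(ValueError, match="spatial"):
            gradcam(model, rng.random((64, 64)), 0, "flatten")

    def test_deterministic(self, rng):
        model = _toy_model(rng)
        img = rng.random((64, 64))
        a = gradcam(model, img, 0, "stage1.relu")
        b = gradcam(model, img, 0, "stage1.relu")
        np.testing.assert_array_equal(a.heatmap, b.heatmap)


class TestSuperpixels:
    def test_constant_image_gives_regular_partition(self):
        img = np.full((64, 64), 0.5)
        labels = segment_superpixels(img, 16)
        n = labels.max() + 1
        assert abs(n - 16) <= 0.3 * 16
        # a partition: every pixel labeled, labels consecutive
        assert set(np.unique(labels)) == set(range(n))
        # roughly equal region sizes on a constant image
        sizes = np.bincount(labels.ravel())
        assert sizes.min() > 0.4 * sizes.mean()

    def test_two_tone_boundary_tracked_within_two_pixels(self):
        img = np.full((128, 128), 0.2)
        img[:, 70:] = 0.8
        labels = segment_superpixels(img, 2)
        assert labels.max() + 1 == 2
        # per row, the label transition must happen at column 70 +/- 2
        for row in range(0, 128, 8):
            cols = np.nonzero(np.diff(labels[row]) != 0)[0]
            assert len(cols) == 1
            assert abs((cols[0] + 1) - 70) <= 2

    def test_count_within_30_percent_on_textured_image(self, rng):
        img = rng.random((128, 128))
        for target in (20, 50):
            labels = segment_superpixels(img, target)
            n = labels.max() + 1
            assert abs(n - target) <= 0.3 * target

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            segment_superpixels(np.zeros((32, 32)), 1)


class TestLIME:
    def test_constant_black_box_gives_zero_coefficients(self, rng):
        img = rng.random((64, 64))
        config = ExplainerConfig(superpixels=10, samples=300)
        result = lime_explain(lambda masks: np.full(len(masks), 0.7),
                              img, 0, config, seed=1)
        np.testing.assert_allclose(result.coefficients, 0.0, atol=1e-8)
        assert result.intercept == pytest.approx(0.7)

    def test_additive_black_box_recovered(self, rng):
        img = rng.random((64, 64))
        config = ExplainerConfig(superpixels=8, samples=1000, ridge=1e-6)
        result = lime_explain(lambda masks: 2.0 * masks[:, 3] + 0.1,
                              img, 0, config, seed=2)
        assert result.coefficients[3] == pytest.approx(2.0, abs=0.05)
        others = np.delete(result.coefficients, 3)
        np.testing.assert_allclose(others, 0.0, atol=0.05)
        assert 3 in result.top_regions

    def test_negative_contribution_lands_in_red_mask(self, rng):
        img = rng.random((64, 64))
        config = ExplainerConfig(superpixels=8, samples=600)
        result = lime_explain(lambda masks: 1.0 - masks[:, 2].astype(float),
                              img, 0, config, seed=3)
        assert result.coefficients[2] < 0
        region2 = result.segments == 2
        assert (result.negative_mask & region2).sum() == region2.sum()
        assert not (result.positive_mask & region2).any()

    def test_matches_closed_form_weighted_least_squares(self, rng):
        """As ridge -> 0 the surrogate equals exact WLS, computed here
        independently via sqrt-weight rescaling and lstsq."""
        from gallnet.xai import _ridge_fit
        masks = rng.random((200, 6)) < 0.5
        masks[0] = True
        responses = rng.random(200)
        d = 1.0 - masks.mean(axis=1)
        weights = np.exp(-(d ** 2) / 0.25 ** 2)
        coef, intercept = _ridge_fit(masks, responses, weights, ridge=1e-12)
        xa = np.column_stack([np.ones(200), masks.astype(float)])
        sw = np.sqrt(weights)
        beta, *_ = np.linalg.lstsq(xa * sw[:, None], responses * sw,
                                   rcond=None)
        np.testing.assert_allclose(coef, beta[1:], atol=1e-6)
        assert intercept == pytest.approx(beta[0], abs=1e-6)

    def test_deterministic_per_seed(self, rng):
        img = rng.random((64, 64))
        config = ExplainerConfig(superpixels=8, samples=200)
        fn = lambda masks: masks.mean(axis=1)  # noqa: E731
        a = lime_explain(fn, img, 0, config, seed=9)
        b = lime_explain(fn, img, 0, config, seed=9)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_undersampled_surrogate_rejected(self, rng):
        img = rng.random((64, 64))
        config = ExplainerConfig(superpixels=40, samples=10)
        with pytest.raises(ValueError, match="samples"):
            lime_explain(lambda m: m.mean(axis=1), img, 0, config, seed=0)

    def test_positive_and_negative_masks_are_disjoint_superpixel_unions(self, rng):
        img = rng.random((64, 64))
        config = ExplainerConfig(superpixels=8, samples=400)
        result = lime_explain(lambda m: m[:, 0] - 0.5 * m[:, 1], img, 0,
                              config, seed=4)
        assert not (result.positive_mask & result.negative_mask).any()
        for mask in (result.positive_mask, result.negative_mask):
            covered = np.unique(result.segments[mask])
            for region in covered:
                region_mask = result.segments == region
                assert (mask & region_mask).sum() == region_mask.sum()


class TestRenderOverlay:
    def test_alpha_zero_returns_replicated_base(self, rng):
        base = rng.random((32, 32))
        result = GradCAMResult(heatmap=rng.random((32, 32)),
                               raw=np.zeros((4, 4)), layer_name="l",
                               class_index=0)
        out = render_overlay(base, result, alpha=0.0)
        np.testing.assert_allclose(out, np.repeat(base[:, :, None], 3, axis=2))

    def test_zero_heatmap_renders_coldest_color(self):
        base = np.zeros((16, 16))
        result = GradCAMResult(heatmap=np.zeros((16, 16)),
                               raw=np.zeros((4, 4)), layer_name="l",
                               class_index=0)
        out = render_overlay(base, result, alpha=1.0)
        cold = np.asarray(colormaps["jet"](0.0))[:3]
        np.testing.assert_allclose(out, np.broadcast_to(cold, (16, 16, 3)))

    def test_lime_pixels_outside_masks_equal_base(self, rng):
        base = rng.random((32, 32))
        segments = (np.arange(32 * 32) % 4).reshape(32, 32)
        pos = segments == 0
        neg = segments == 2
        result = LIMEResult(segments=segments, coefficients=np.zeros(4),
                            intercept=0.0, top_regions=[0, 2],
                            positive_mask=pos, negative_mask=neg, seed=0)
        out = render_overlay(base, result, alpha=0.5)
        outside = ~(pos | neg)
        np.testing.assert_array_equal(
            out[outside], np.repeat(base[:, :, None], 3, axis=2)[outside])

    def test_shape_mismatch_rejected(self, rng):
        base = rng.random((32, 32))
        result = GradCAMResult(heatmap=np.zeros((16, 16)),
                               raw=np.zeros((4, 4)), layer_name="l",
                               class_index=0)
        with pytest.raises(ValueError, match="shape"):
            render_overlay(base, result)
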