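"""Topology, shape propagation, focal loss and the training loop."""

import numpy as np
import pandas as pd
import pytest

from hsipatho import nn
from hsipatho.errors import LeakageError, ParameterError, ShapeError, TopologyError
from hsipatho.model import (
    FocalLossParams,
    TopologySpec,
    TrainConfig,
    build_classifier,
    conv3d_reference,
    focal_loss,
    focal_loss_grad,
    load_checkpoint,
    predict_patches,
    predict_probabilities,
    propagate_shapes,
    save_checkpoint,
    train_classifier,
)
from hsipatho.preprocess import PatchSet


def shapes_by_name(spec, dims):
    return dict(propagate_shapes(spec, dims))


class TestShapePropagation:
    def test_reference_topology_output_sizes(self):
        """Every pooled feature-map size of the reference 4-block topology on a
        100 x 100 x 270 input, including the ceil behaviour on odd extents."""
        shapes = shapes_by_name(TopologySpec.default_3d(), (100, 100, 270))
        assert shapes["conv1"] == (100, 100, 270, 4)
        assert shapes["pool1"] == (50, 50, 135, 4)
        assert shapes["pool2"] == (25, 25, 68, 8)
        assert shapes["pool3"] == (13, 13, 34, 16)
        assert shapes["pool4"] == (7, 7, 17, 32)
        assert shapes["global_average_pool"] == (32,)
        assert shapes["dense"] == (512,)
        assert shapes["output"] == (1,)

    def test_unit_input_is_fixed_point_of_pooling(self):
        shapes = shapes_by_name(TopologySpec.default_3d(), (1, 1, 1))
        for i in range(1, 5):
            assert shapes[f"pool{i}"][:3] == (1, 1, 1)

    def test_repeated_ceiling_division(self):
        shapes = shapes_by_name(TopologySpec.default_3d(), (8, 8, 8))
        assert [shapes[f"pool{i}"][:3] for i in range(1, 5)] == [
            (4, 4, 4), (2, 2, 2), (1, 1, 1), (1, 1, 1),
        ]

    def test_2d_variant_pools_space_only(self):
        shapes = shapes_by_name(TopologySpec.default_2d(), (64, 64, 30))
        assert shapes["pool1"] == (32, 32, 4)
        assert shapes["pool4"] == (4, 4, 32)

    def test_non_positive_input_raises(self):
        with pytest.raises(TopologyError):
            propagate_shapes(TopologySpec.default_3d(), (0, 10, 10))

    def test_filter_doubling_is_enforced(self):
        with pytest.raises(TopologyError):
            TopologySpec(filters=(4, 8, 12, 24))
        with pytest.raises(TopologyError):
            TopologySpec(filters=(4, 8, 16))


class TestFocalLoss:
    def test_perfect_prediction_has_zero_loss(self):
        for gamma, alpha in [(0.0, 0.3), (2.0, 0.5), (5.0, 1.0)]:
            params = FocalLossParams(gamma=gamma, alpha=alpha)
            assert focal_loss(1.0, 1, params) == pytest.approx(0.0, abs=1e-5)

    def test_reduces_to_plain_cross_entropy(self):
        params = FocalLossParams.cross_entropy()
        assert focal_loss(np.exp(-1.0), 1, params) == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_value(self):
        params = FocalLossParams(gamma=2.0, alpha=0.5)
        expected = 0.5 * 0.25 * -np.log(0.5)
        assert focal_loss(0.5, 1, params) == pytest.approx(expected, abs=1e-6)
        assert focal_loss(0.5, 1, params) == pytest.approx(0.08664, abs=1e-5)

    def test_gamma_zero_equals_balanced_cross_entropy(self):
        """On a 100-point grid of p_t, the focal loss with gamma = 0 coincides
        with -alpha_t log(p_t) to 1e-10 for both classes."""
        pts = np.linspace(0.01, 1.0, 100)
        for alpha in (0.25, 0.5, 0.75):
            params = FocalLossParams(gamma=0.0, alpha=alpha)
            np.testing.assert_allclose(
                focal_loss(pts, np.ones(100, dtype=int), params),
                -alpha * np.log(pts),
                atol=1e-10,
            )
            np.testing.assert_allclose(
                focal_loss(1.0 - pts, -np.ones(100, dtype=int), params),
                -(1 - alpha) * np.log(pts),
                atol=1e-10,
            )

    def test_strictly_decreasing_in_pt(self):
        pts = np.linspace(0.02, 0.98, 200)
        losses = focal_loss(pts, np.ones(200, dtype=int), FocalLossParams(2.0, 0.5))
        assert np.all(np.diff(losses) < 0)

    def test_focusing_downweights_easy_examples_progressively(self):
        """FL(gamma_hi)/FL(gamma_lo) decreases in p_t: confident (easy)
        examples lose relatively more loss as gamma grows."""
        pts = np.linspace(0.05, 0.95, 100)
        y = np.ones(100, dtype=int)
        for lo, hi in [(0.0, 2.0), (1.5, 2.5)]:
            ratio = focal_loss(pts, y, FocalLossParams(hi, 0.5)) / focal_loss(
                pts, y, FocalLossParams(lo, 0.5)
            )
            assert np.all(np.diff(ratio) < 0)

    def test_alpha_weights_the_two_classes(self):
        params = FocalLossParams(gamma=0.0, alpha=0.25)
        pos = focal_loss(0.3, 1, params)  # a_t = 0.25
        neg = focal_loss(0.7, -1, params)  # same p_t, a_t = 0.75
        assert neg == pytest.approx(3.0 * pos)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ParameterError):
            FocalLossParams(gamma=-0.5, alpha=0.5)
        with pytest.raises(ParameterError):
            FocalLossParams(gamma=2.0, alpha=1.5)

    def test_gradient_matches_finite_differences(self):
        params = FocalLossParams(2.0, 0.25)
        for p in (0.2, 0.5, 0.9):
            for y in (1, -1):
                eps = 1e-6
                num = (focal_loss(p + eps, y, params) - focal_loss(p - eps, y, params)) / (2 * eps)
                assert focal_loss_grad(p, y, params) == pytest.approx(num, rel=1e-5)


class TestConvolutionOracle:
    def test_zero_kernels_give_zero_output(self):
        x = np.ones((4, 4, 4, 1))
        out = conv3d_reference(x, np.zeros((1, 3, 3, 3, 2)), np.zeros(2))
        np.testing.assert_array_equal(out, 0.0)

    def test_unit_kernel_is_relu_of_input(self, rng):
        x = rng.standard_normal((4, 5, 3, 1))
        kernels = np.ones((1, 1, 1, 1, 1))
        out = conv3d_reference(x, kernels, np.zeros(1))
        np.testing.assert_allclose(out[..., 0], np.maximum(x[..., 0], 0.0))

    def test_backend_matches_reference_on_random_tensors(self, rng):
        """The vectorised/compiled backend reproduces the explicit sextuple-sum
        convolution on 20 random small tensors within 1e-5 relative error."""
        for _ in range(20):
            dims = tuple(rng.integers(2, 7, size=3))
            cin, f = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            x = rng.standard_normal((*dims, cin))
            kernels = rng.standard_normal((cin, 3, 3, 3, f))
            biases = rng.standard_normal(f)
            reference = conv3d_reference(x, kernels, biases)
            conv = nn.ConvND((3, 3, 3), cin, f, rng)
            conv.params["W"] = kernels
            conv.params["b"] = biases
            backend = conv.forward(np.moveaxis(x, -1, 0)[None], False, None)[0]
            backend = np.moveaxis(backend, 0, -1)
            np.testing.assert_allclose(backend, reference, rtol=1e-5, atol=1e-8)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ShapeError):
            conv3d_reference(np.zeros((2, 2, 2, 3)), np.zeros((1, 3, 3, 3, 1)), np.zeros(1))


class TestBuildClassifier:
    def test_3d_build_matches_reference_filter_counts(self):
        net = build_classifier(None, "3d", (100, 100, 270), seed=0)
        convs = [l for l in net.layers if isinstance(l, nn.ConvND)]
        assert [c.filters for c in convs] == [4, 8, 16, 32]
        assert convs[0].params["W"].shape == (1, 3, 3, 3, 4)
        dense = [l for l in net.layers if isinstance(l, nn.Dense)]
        assert dense[0].params["W"].shape == (32, 512)
        assert dense[1].params["W"].shape == (512, 1)

    def test_2d_build_folds_bands_into_channels(self):
        net = build_classifier(None, "2d", (100, 100, 270), seed=0)
        first = next(l for l in net.layers if isinstance(l, nn.ConvND))
        assert first.params["W"].shape == (270, 3, 3, 4)

    def test_desk_scale_3d_build_is_valid(self):
        net = build_classifier(None, "3d", (32, 32, 30), seed=0)
        x = np.zeros((2, 1, 32, 32, 30), dtype=np.float32)
        assert net.forward(x).shape == (2, 1)

    def test_rgb_input_caps_spectral_kernel_and_stride(self):
        spec = TopologySpec.default_3d(3)
        assert spec.kernel == (3, 3, 3) and spec.pool_stride == (2, 2, 1)
        shapes = shapes_by_name(spec, (32, 32, 3))
        assert shapes["pool4"] == (2, 2, 3, 32)
        net = build_classifier(spec, "3d", (32, 32, 3), seed=0)
        assert net.forward(np.zeros((2, 1, 32, 32, 3), dtype=np.float32)).shape == (2, 1)


def _separable_patchset(rng, n=200, s=8, b=8, cases=("a", "b", "c", "d")):
    """Two spectrally distinct constant patch populations, linearly separable."""
    y = rng.random(n) < 0.5
    base = np.where(y[:, None], 0.7, 0.4) + 0.01 * rng.standard_normal((n, b))
    values = np.broadcast_to(base[:, None, None, :], (n, s, s, b)).copy()
    values += 0.01 * rng.standard_normal(values.shape)
    return PatchSet(
        values=values.astype(np.float32),
        labels=np.where(y, "unhealthy", "healthy"),
        case_ids=rng.choice(cases, size=n),
    )


class TestTraining:
    def test_first_epoch_loss_finite_and_positive(self, rng):
        train = _separable_patchset(rng, n=24)
        net = build_classifier(None, "3d", (8, 8, 8), seed=0)
        cfg = TrainConfig.desk(epochs=1, patch_size=8, n_bands=8)
        _, history = train_classifier(net, train, None, FocalLossParams(2.0, 0.5), cfg)
        loss = history["train_loss"].iloc[0]
        assert np.isfinite(loss) and loss > 0

    def test_same_seed_gives_bit_identical_history(self, rng):
        train = _separable_patchset(rng, n=24)
        histories = []
        for _ in range(2):
            net = build_classifier(None, "3d", (8, 8, 8), seed=7)
            cfg = TrainConfig.desk(seed=11, epochs=2, patch_size=8, n_bands=8)
            _, h = train_classifier(net, train, None, FocalLossParams(2.0, 0.5), cfg)
            histories.append(h)
        pd.testing.assert_frame_equal(histories[0], histories[1])

    def test_learns_linearly_separable_patches(self, rng):
        """A scaled-down 3D model fits a 200-patch separable set to >= 95%
        training accuracy within 15 epochs."""
        train = _separable_patchset(rng, n=200)
        net = build_classifier(None, "3d", (8, 8, 8), seed=0)
        cfg = TrainConfig.desk(seed=0, epochs=15, patch_size=8, n_bands=8)
        net, history = train_classifier(net, train, None, FocalLossParams(2.0, 0.5), cfg)
        assert history["train_accuracy"].iloc[-1] >= 0.95

    def test_case_overlap_between_splits_is_a_hard_error(self, rng):
        train = _separable_patchset(rng, n=20, cases=("a", "b"))
        val = _separable_patchset(rng, n=10, cases=("b", "c"))
        net = build_classifier(None, "3d", (8, 8, 8), seed=0)
        with pytest.raises(LeakageError):
            train_classifier(net, train, val, FocalLossParams(), TrainConfig.desk())

    def test_checkpoint_round_trip_preserves_predictions(self, rng, tmp_path):
        train = _separable_patchset(rng, n=40)
        net = build_classifier(None, "3d", (8, 8, 8), seed=0)
        cfg = TrainConfig.desk(seed=0, epochs=2, patch_size=8, n_bands=8)
        net, _ = train_classifier(net, train, None, FocalLossParams(2.0, 0.5), cfg)
        before = predict_probabilities(net, train)
        path = save_checkpoint(net, tmp_path / "model.npz", loss=FocalLossParams(), cfg=cfg)
        fresh = build_classifier(None, "3d", (8, 8, 8), seed=99)
        load_checkpoint(fresh, path)
        np.testing.assert_allclose(predict_probabilities(fresh, train), before, atol=1e-6)
        assert (tmp_path / "model.npz.json").exists()


class TestPrediction:
    class _Stub(nn.Network):
        def __init__(self, probs):
            super().__init__([], variant="3d", input_dims=None)
            self._probs = np.asarray(probs, dtype=np.float32)

        def forward(self, x, train=False, rng=None):
            return self._probs[: len(x), None]

    def _patches(self, n):
        return PatchSet(
            values=np.zeros((n, 4, 4, 2), dtype=np.float32),
            labels=np.array(["healthy"] * n),
            case_ids=np.array(["c"] * n),
        )

    def test_decision_threshold_is_strict(self):
        labels, probs = predict_patches(self._Stub([1.0, 0.0, 0.5]), self._patches(3))
        assert labels.tolist() == ["unhealthy", "healthy", "healthy"]
        np.testing.assert_allclose(probs, [1.0, 0.0, 0.5])

    def test_dimension_mismatch_raises(self, rng):
        net = build_classifier(None, "3d", (8, 8, 8), seed=0)
        bad = PatchSet(
            values=rng.random((2, 6, 6, 8)).astype(np.float32),
            labels=np.array(["healthy", "healthy"]),
            case_ids=np.array(["a", "a"]),
        )
        with pytest.raises(ShapeError):
            predict_patches(net, bad)
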