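"""Tests of the CCNN / simple / deep classifiers and their bookkeeping."""

import numpy as np
import pytest

from ccnn import models
from ccnn.datasets import ConnectomeDataset
from ccnn.models import (
    ModelConfig,
    build,
    conv1_forward,
    count_trainable_weights,
    flatten_features,
    predict_proba,
    train,
)


class TestWeightCounts:
    @pytest.mark.parametrize(
        "kind,n,c,expected_w,expected_b",
        [
            # printed full-scale parameter counts
            ("ccnn", 499, 1, 4_132_224, 290),
            ("ccnn", 499, 2, 4_164_160, 290),
            ("simple", 499, 1, 15_904_384, 130),
            ("simple", 499, 2, 31_808_512, 130),
            ("deep", 499, 1, 15_916_608, 226),
            ("deep", 499, 2, 31_820_736, 226),
            # hand-evaluated small case: 10*64 + 10*64*128 + 128*96 + 96*2
            ("ccnn", 10, 1, 95_040, 290),
        ],
    )
    def test_closed_form_counts(self, kind, n, c, expected_w, expected_b):
        cfg = ModelConfig(kind=kind, n_rois=n, n_channels=c)
        assert count_trainable_weights(cfg) == (expected_w, expected_b)

    @pytest.mark.parametrize("kind", ["ccnn", "simple", "deep"])
    @pytest.mark.parametrize("n,c", [(10, 1), (10, 2), (499, 1), (499, 2)])
    def test_instantiated_model_matches_closed_form(self, kind, n, c):
        cfg = ModelConfig(kind=kind, n_rois=n, n_channels=c)
        model = build(cfg)
        assert model.parameter_counts() == count_trainable_weights(cfg)

    def test_channel_growth_contrast(self):
        # adding a channel grows the CCNN by N*64 weights (<1% at
        # N=499) while it nearly doubles the dense models
        def growth(kind):
            w1, _ = count_trainable_weights(ModelConfig(kind=kind, n_rois=499))
            w2, _ = count_trainable_weights(
                ModelConfig(kind=kind, n_rois=499, n_channels=2)
            )
            return w1, w2

        w1, w2 = growth("ccnn")
        assert w2 - w1 == 499 * 64
        assert (w2 - w1) / w1 < 0.01
        for kind in ("simple", "deep"):
            w1, w2 = growth(kind)
            assert w2 - w1 == 499 * 498 // 2 * 128
            assert w2 / w1 > 1.95


class TestFlattenFeatures:
    def test_feature_counts(self):
        def make(n, c):
            data = np.zeros((3, c, n, n))
            return ConnectomeDataset(
                data=data, labels=[0, 1, 0], group_ids=[0, 1, 2],
                channel_names=[f"m{i}" for i in range(c)],
            )

        assert flatten_features(make(2, 1)).shape == (3, 1)
        assert flatten_features(make(4, 2)).shape == (3, 12)
        cfg = ModelConfig(kind="simple", n_rois=499)
        assert cfg.n_features == 124_251

    def test_row_major_upper_triangle_order(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        ds = ConnectomeDataset(
            data=m[None, None], labels=[0], group_ids=[0], channel_names=["x"]
        )
        assert np.array_equal(flatten_features(ds)[0], [1.0, 2.0, 3.0])

    def test_asymmetric_input_rejected(self):
        data = np.zeros((1, 1, 3, 3))
        ds = ConnectomeDataset(
            data=data, labels=[0], group_ids=[0], channel_names=["x"]
        )
        ds.data[0, 0, 0, 1] = 1e-3  # corrupt after validation
        with pytest.raises(ValueError, match="asymmetric"):
            flatten_features(ds)


class TestForward:
    def test_softmax_output_normalized(self, separable_dataset):
        cfg = ModelConfig(kind="ccnn", n_rois=8, seed=0, epochs=2)
        model = train(build(cfg), separable_dataset, np.arange(20))
        probs = predict_proba(model, separable_dataset, np.arange(20))
        assert probs.shape == (20, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_input_conv1_is_bias(self):
        cfg = ModelConfig(kind="ccnn", n_rois=6, seed=1)
        model = build(cfg)
        model.biases["conv1"] = np.linspace(-1, 1, 64)
        x = np.zeros((2, 1, 6, 6))
        out = conv1_forward(x, model.weights["conv1"], model.biases["conv1"])
        assert np.allclose(out, np.broadcast_to(np.linspace(-1, 1, 64), (2, 6, 64)))

    def test_roi_permutation_covariance(self):
        # permuting ROIs in the input together with the fingerprint
        # weights permutes conv1's per-ROI outputs and nothing else
        rng = np.random.default_rng(0)
        n = 7
        x = rng.standard_normal((3, 2, n, n))
        x = (x + np.swapaxes(x, -1, -2)) / 2
        w = rng.standard_normal((64, 2, n))
        b = rng.standard_normal(64)
        perm = rng.permutation(n)
        x_p = x[:, :, perm][:, :, :, perm]
        w_p = w[:, :, perm]
        out = conv1_forward(x, w, b)
        out_p = conv1_forward(x_p, w_p, b)
        assert np.allclose(out_p, out[:, perm, :])

    def test_duplicated_instance_identical_rows(self, separable_dataset):
        cfg = ModelConfig(kind="deep", n_rois=8, seed=0, epochs=2)
        model = train(build(cfg), separable_dataset, np.arange(20))
        probs = predict_proba(model, separable_dataset, [3, 3])
        assert np.array_equal(probs[0], probs[1])


class TestTraining:
    @pytest.mark.parametrize("kind", ["ccnn", "simple", "deep"])
    def test_capacity_on_separable_toy(self, kind, separable_dataset):
        cfg = ModelConfig(kind=kind, n_rois=8, seed=0, epochs=80)
        model = train(build(cfg), separable_dataset, np.arange(20))
        probs = predict_proba(model, separable_dataset, np.arange(20))
        acc = np.mean(probs.argmax(axis=1) == separable_dataset.labels)
        assert acc == 1.0

    def test_heldout_accuracy_on_separable_toy(self, separable_dataset):
        train_idx = np.concatenate([np.arange(7), np.arange(10, 17)])
        test_idx = np.concatenate([np.arange(7, 10), np.arange(17, 20)])
        cfg = ModelConfig(kind="ccnn", n_rois=8, seed=0, epochs=80)
        model = train(build(cfg), separable_dataset, train_idx)
        probs = predict_proba(model, separable_dataset, test_idx)
        assert np.mean(probs.argmax(axis=1) == separable_dataset.labels[test_idx]) == 1.0

    def test_loss_decreases(self, separable_dataset):
        cfg = ModelConfig(kind="ccnn", n_rois=8, seed=0, epochs=30)
        model = train(build(cfg), separable_dataset, np.arange(20))
        log = model.training_log
        assert log[-1] <= log[0]

    def test_training_deterministic(self, separable_dataset):
        cfg = ModelConfig(kind="ccnn", n_rois=8, seed=42, epochs=10)
        a = train(build(cfg), separable_dataset, np.arange(20))
        b = train(build(cfg), separable_dataset, np.arange(20))
        for name in a.weights:
            assert np.array_equal(a.weights[name], b.weights[name])

    def test_single_class_training_rejected(self, separable_dataset):
        cfg = ModelConfig(kind="ccnn", n_rois=8, seed=0)
        with pytest.raises(ValueError, match="single class"):
            train(build(cfg), separable_dataset, np.arange(10))

    def test_shape_mismatch_rejected(self, separable_dataset, small_dataset):
        cfg = ModelConfig(kind="ccnn", n_rois=8, seed=0, epochs=2)
        model = train(build(cfg), separable_dataset, np.arange(20))
        with pytest.raises(ValueError, match="incompatible"):
            predict_proba(model, small_dataset, [0])

    def test_standardization_uses_training_statistics(self, separable_dataset):
        cfg = ModelConfig(kind="ccnn", n_rois=8, seed=0, epochs=2)
        model = train(build(cfg), separable_dataset, np.arange(5, 15))
        stats = models._standardize_stats(separable_dataset.data[5:15])
        assert np.array_equal(model.channel_mean, stats[0])
        assert np.array_equal(model.channel_std, stats[1])


class TestConfigValidation:
    def test_bad_kind(self):
        with pytest.raises(ValueError):
            ModelConfig(kind="cnn", n_rois=10)

    def test_bad_keep_prob(self):
        with pytest.raises(ValueError):
            ModelConfig(kind="ccnn", n_rois=10, keep_prob=0.0)

    def test_default_optimizers(self):
        assert ModelConfig(kind="simple", n_rois=10).optimizer == "sgd"
        assert ModelConfig(kind="ccnn", n_rois=10).optimizer == "adam"
        assert ModelConfig(kind="deep", n_rois=10).optimizer == "adam"
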