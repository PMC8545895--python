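import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgrasp import RunConfig, build_cnn, predict, train_cnn, train_svm
from emgrasp.classifiers import TrainedModel, forward_probs, _im2col


def brute_force_conv(grids, w, b, k):
    """Direct nested-loop valid convolution oracle, [n x P x M]."""
    n, s, _, c = grids.shape
    m = w.shape[1]
    out_side = s - k + 1
    out = np.zeros((n, out_side * out_side, m))
    for ni in range(n):
        p = 0
        for i in range(out_side):
            for j in range(out_side):
                patch = grids[ni, i : i + k, j : j + k, :]
                for f in range(m):
                    kern = w[:, f].reshape(k, k, c)
                    out[ni, p, f] = np.sum(patch * kern) + b[f]
                p += 1
    return out


def _separable_grids(n_per_class, n_classes, n_ch, seed):
    """Class-dependent mean grids + small noise: linearly separable."""
    rng = np.random.default_rng(seed)
    centers = 3.0 * rng.standard_normal((n_classes, 5, 5, n_ch))
    grids, labels = [], []
    for c in range(n_classes):
        grids.append(centers[c] + 0.1 * rng.standard_normal((n_per_class, 5, 5, n_ch)))
        labels += [f"class{c}"] * n_per_class
    return np.concatenate(grids), np.array(labels)


class TestBuildCnn:
    def test_parameter_count_six_channels_six_classes(self, cfg):
        spec = build_cnn(6, 6, cfg)
        assert spec.param_count == 38_800 + 640_400 + 2_406 == 681_606
        assert (spec.conv_out, spec.flatten) == (2, 1600)

    def test_conv_parameters_eight_channels(self, cfg):
        spec = build_cnn(8, 6, cfg)
        conv_params = 4 * 4 * 8 * 400 + 400
        assert conv_params == 51_600
        assert spec.param_count == conv_params + 1600 * 400 + 400 + 400 * 6 + 6

    def test_single_class_rejected(self, cfg):
        with pytest.raises(ValueError):
            build_cnn(6, 1, cfg)

    def test_oversized_kernel_rejected(self, cfg):
        with pytest.raises(ValueError):
            build_cnn(6, 6, cfg.replace(conv_kernel=6))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.integers(1, 8), k=st.integers(2, 12))
    def test_parameter_count_formula(self, c, k, cfg):
        spec = build_cnn(c, k, cfg)
        expected = (
            (4 * 4 * c * 400 + 400) + (1600 * 400 + 400) + (400 * k + k)
        )
        assert spec.param_count == expected


class TestCnnForward:
    def test_conv_matches_direct_convolution_oracle(self, cfg, rng):
        grids = rng.standard_normal((3, 5, 5, 6))
        w = rng.standard_normal((4 * 4 * 6, 10))
        b = rng.standard_normal(10)
        cols = _im2col(grids, 4)
        ours = cols @ w + b
        oracle = brute_force_conv(grids, w, b, 4)
        np.testing.assert_allclose(ours, oracle, rtol=1e-6, atol=1e-9)

    def test_probabilities_sum_to_one(self, cfg):
        grids, labels = _separable_grids(20, 3, 6, seed=0)
        spec = build_cnn(6, 3, cfg.replace(epochs=3))
        model = train_cnn(spec, grids, labels, seed=0, cfg=cfg.replace(epochs=3))
        _, probs = predict(model, grids)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_tie_breaks_to_lowest_class_index(self, cfg):
        spec = build_cnn(6, 3, cfg)
        model = train_cnn(
            spec, *_separable_grids(12, 3, 6, seed=1), seed=0, cfg=cfg.replace(epochs=1)
        )
        # zero the output layer: uniform logits, a 3-way tie on every input
        model.weights["W3"][:] = 0.0
        model.weights["b3"][:] = 0.0
        labels, probs = predict(model, np.zeros((4, 5, 5, 6), dtype=np.float32))
        np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-6)
        assert all(lab == model.classes_[0] for lab in labels)


class TestCnnTraining:
    def test_separable_data_fits_to_high_accuracy(self, cfg):
        grids, labels = _separable_grids(100, 2, 6, seed=3)
        spec = build_cnn(6, 2, cfg)
        model = train_cnn(spec, grids, labels, seed=0, cfg=cfg)
        pred, _ = predict(model, grids)
        assert np.mean(pred == labels) >= 0.99

    def test_training_is_bit_deterministic(self, cfg):
        grids, labels = _separable_grids(30, 2, 6, seed=4)
        fast = cfg.replace(epochs=5)
        spec = build_cnn(6, 2, fast)
        a = train_cnn(spec, grids, labels, seed=11, cfg=fast)
        b = train_cnn(spec, grids, labels, seed=11, cfg=fast)
        assert a.loss_history == b.loss_history
        for name in a.weights:
            np.testing.assert_array_equal(a.weights[name], b.weights[name])

    def test_loss_decreases_overall(self, cfg):
        grids, labels = _separable_grids(50, 2, 6, seed=5)
        model = train_cnn(build_cnn(6, 2, cfg), grids, labels, seed=0, cfg=cfg)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_missing_class_rejected(self, cfg):
        grids, labels = _separable_grids(10, 2, 6, seed=6)
        spec = build_cnn(6, 3, cfg)
        with pytest.raises(ValueError, match="class"):
            train_cnn(spec, grids, labels, seed=0, cfg=cfg)

    def test_two_stage_variant_trains(self, cfg):
        two = cfg.replace(cnn_two_stage=True, epochs=30)
        grids, labels = _separable_grids(40, 2, 6, seed=7)
        spec = build_cnn(6, 2, two)
        assert spec.flatten == 400
        assert spec.param_count == (4 * 4 * 6 * 400 + 400) + (4 * 400 * 400 + 400) + (
            400 * 400 + 400
        ) + (400 * 2 + 2)
        model = train_cnn(spec, grids, labels, seed=0, cfg=two)
        pred, _ = predict(model, grids)
        assert np.mean(pred == labels) >= 0.9


class TestSvm:
    def test_separable_features_fit(self, cfg, rng):
        x = np.concatenate([rng.standard_normal((50, 48)), 6 + rng.standard_normal((50, 48))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        model = train_svm(x, y, cfg, seed=0)
        pred, probs = predict(model, x)
        assert np.mean(pred == y) >= 0.99
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_given_seed(self, cfg, rng):
        x = rng.standard_normal((60, 10))
        y = np.array(["a", "b", "c"] * 20)
        p1, _ = predict(train_svm(x, y, cfg, seed=5), x)
        p2, _ = predict(train_svm(x, y, cfg, seed=5), x)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, cfg):
        with pytest.raises(ValueError):
            train_svm(np.zeros((10, 4)), np.array(["a"] * 10), cfg)

    def test_feature_dimension_checked_at_predict(self, cfg, rng):
        x = rng.standard_normal((20, 8))
        y = np.array(["a", "b"] * 10)
        model = train_svm(x, y, cfg, seed=0)
        with pytest.raises(ValueError):
            predict(model, rng.standard_normal((5, 9)))
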