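"""Classifier: shapes, forward semantics, gradients, and training behavior."""

import numpy as np
import pytest

from cardiovault.cohort import CohortSpec, generate_cohort, feature_matrix, split
from cardiovault.net import (
    NetworkConfig,
    build_model,
    forward,
    load_model,
    loss_and_grads,
    predict,
    save_model,
    train,
    tuned_config,
)


def central_difference_check(cfg, n=7, eps=1e-6, seed=0):
    """Worst relative disagreement between analytic and finite-difference
    gradients over every trainable parameter of a probe net."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, cfg.input_dim))
    y = rng.integers(0, 2, n)
    params = build_model(cfg)
    _, grads = loss_and_grads(params, X, y, training=True, rng_seed=42)
    worst = 0.0
    for k, g in grads.items():
        a = params.arrays[k]
        for ij in np.ndindex(*a.shape):
            orig = a[ij]
            a[ij] = orig + eps
            lp, _ = loss_and_grads(params, X, y, training=True, rng_seed=42)
            a[ij] = orig - eps
            lm, _ = loss_and_grads(params, X, y, training=True, rng_seed=42)
            a[ij] = orig
            fd = (lp - lm) / (2 * eps)
            worst = max(worst, abs(fd - g[ij]) / max(1e-8, abs(fd) + abs(g[ij])))
    return worst


class TestBuild:
    def test_dense_parameter_count(self):
        cfg = NetworkConfig(use_conv=False, dense_units=100, input_dim=13)
        assert build_model(cfg).n_parameters() == 13 * 100 + 100 + 100 * 2 + 2

    def test_default_dense_units(self):
        assert NetworkConfig().dense_units == 100

    def test_seeded_init_identical(self):
        cfg = NetworkConfig(seed=5)
        a = build_model(cfg).arrays
        b = build_model(cfg).arrays
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_dim=0)
        with pytest.raises(ValueError):
            NetworkConfig(dropout_rate=1.0)


class TestForward:
    def test_zero_weights_uniform_softmax(self):
        cfg = NetworkConfig(input_dim=4, dense_units=3, dropout_rate=0.0)
        params = build_model(cfg)
        for k in params.arrays:
            params.arrays[k][:] = 0.0
        probs = forward(params, np.ones((5, 4)))
        assert np.allclose(probs, 0.5)

    def test_rows_sum_to_one(self, rng):
        cfg = NetworkConfig(input_dim=13, use_conv=True, seed=2)
        params = build_model(cfg)
        probs = forward(params, rng.normal(size=(20, 13)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_inference_ignores_dropout_rng(self, rng):
        cfg = NetworkConfig(input_dim=5, dropout_rate=0.5, seed=1)
        params = build_model(cfg)
        X = rng.normal(size=(6, 5))
        p1 = forward(params, X, training=False)
        p2 = forward(params, X, training=False,
                     rng=np.random.default_rng(999))
        assert np.array_equal(p1, p2)

    def test_nan_input_names_row(self):
        cfg = NetworkConfig(input_dim=3)
        params = build_model(cfg)
        X = np.ones((4, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValueError, match="row 2"):
            forward(params, X)

    def test_shape_mismatch(self):
        params = build_model(NetworkConfig(input_dim=13))
        with pytest.raises(ValueError):
            forward(params, np.ones((2, 5)))


class TestGradients:
    @pytest.mark.parametrize("cfg", [
        NetworkConfig(input_dim=6, dense_units=5, dropout_rate=0.3, seed=1),
        NetworkConfig(input_dim=6, use_conv=True, conv_filters=4,
                      dense_units=5, dropout_rate=0.3, seed=1),
        NetworkConfig(input_dim=6, use_conv=True, use_batchnorm=False,
                      conv_filters=4, dense_units=5, dropout_rate=0.0, seed=1),
    ], ids=["dense", "conv-batchnorm", "conv-plain"])
    def test_matches_finite_differences(self, cfg):
        assert central_difference_check(cfg) < 1e-5


class TestTraining:
    def test_zero_learning_rate_is_noop(self, separable_cohort):
        _, _, X, y = separable_cohort
        cfg = NetworkConfig(learning_rate=0.0, epochs=3, seed=0)
        params, report = train(cfg, X[:64], y[:64])
        fresh = build_model(cfg)
        assert all(np.array_equal(params.arrays[k], fresh.arrays[k])
                   for k in fresh.arrays)
        assert len(report.train_loss) == 3

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_separable_cohort_high_accuracy(self, seed):
        spec = CohortSpec(n=400, effect_scale=2.5, seed=50 + seed)
        X, y = feature_matrix(generate_cohort(spec))
        cfg = NetworkConfig(seed=seed)
        _, report = train(cfg, X, y)
        assert report.train_accuracy[-1] >= 0.95

    def test_loss_non_increasing_at_small_lr(self, separable_cohort):
        _, _, X, y = separable_cohort
        cfg = NetworkConfig(learning_rate=1e-3, dropout_rate=0.0, epochs=15,
                            seed=2)
        _, report = train(cfg, X, y)
        assert all(b <= a + 1e-9 for a, b in
                   zip(report.train_loss, report.train_loss[1:]))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 13))
        with pytest.raises(ValueError, match="single class"):
            train(NetworkConfig(), X, np.zeros(20, dtype=int))

    def test_momentum_recorded_in_report(self, separable_cohort):
        _, _, X, y = separable_cohort
        cfg = tuned_config(epochs=2, seed=0)
        _, report = train(cfg, X[:64], y[:64])
        assert report.config.momentum == 0.9
        assert report.config.learning_rate == 1e-4

    def test_determinism(self, separable_cohort):
        _, _, X, y = separable_cohort
        cfg = NetworkConfig(epochs=3, seed=8)
        p1, _ = train(cfg, X[:100], y[:100])
        p2, _ = train(cfg, X[:100], y[:100])
        assert all(np.array_equal(p1.arrays[k], p2.arrays[k])
                   for k in p1.arrays)

    def test_batchnorm_inference_uses_running_moments(self, rng):
        cfg = NetworkConfig(input_dim=6, use_conv=True, conv_filters=4,
                            dense_units=5, dropout_rate=0.0, seed=0)
        params = build_model(cfg)
        X = rng.normal(size=(16, 6))
        p_eval = forward(params, X, training=False)
        # one training-mode pass shifts the running moments...
        forward(params, X, training=True, rng=np.random.default_rng(0))
        p_eval2 = forward(params, X, training=False)
        assert not np.array_equal(p_eval, p_eval2)

    def test_class_weighting_lifts_minority_recall(self):
        """Inverse-frequency weights raise held-out minority recall on a
        9:1 cohort in >= 4 of 5 paired seeds."""
        wins = 0
        for seed in range(5):
            spec = CohortSpec(n=600, prevalence=0.1, effect_scale=1.0,
                              seed=200 + seed)
            records = generate_cohort(spec)
            tr, te = split(records, 0.3, seed=seed)
            X_tr, y_tr = feature_matrix(tr)
            X_te, y_te = feature_matrix(te)
            recalls = []
            for scheme in ("none", "inverse_frequency"):
                cfg = NetworkConfig(class_weighting=scheme, seed=seed)
                params, _ = train(cfg, X_tr, y_tr)
                labels, _ = predict(params, X_te)
                tp = int(((y_te == 1) & (labels == 1)).sum())
                fn = int(((y_te == 1) & (labels == 0)).sum())
                recalls.append(tp / max(1, tp + fn))
            wins += recalls[1] > recalls[0]
        assert wins >= 4


class TestPredict:
    def test_argmax_and_tie_rule(self):
        cfg = NetworkConfig(input_dim=4, dense_units=3, dropout_rate=0.0)
        params = build_model(cfg)
        for k in params.arrays:
            params.arrays[k][:] = 0.0  # every probability exactly (0.5, 0.5)
        labels, probs = predict(params, np.ones((3, 4)))
        assert np.all(labels == 0)  # ties break toward class 0
        assert np.allclose(probs, 0.5)

    def test_round_trip_serialization(self, tmp_path, separable_cohort):
        _, _, X, y = separable_cohort
        cfg = NetworkConfig(epochs=2, seed=1)
        params, _ = train(cfg, X[:80], y[:80])
        path = str(tmp_path / "model.npz")
        save_model(params, path)
        restored = load_model(path)
        l1, p1 = predict(params, X[80:120])
        l2, p2 = predict(restored, X[80:120])
        assert np.array_equal(l1, l2) and np.allclose(p1, p2)
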