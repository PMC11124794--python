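"""Architecture arithmetic, training and prediction of the 1-D CNN."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import posegym as pg
from posegym.cnn import ConfigurationError, IntegrityError, StateError, _backward, _forward


def _brute_force_shapes(input_length, channels, kernel, pool):
    """Independent layer-by-layer recurrence for the shape oracle."""
    L, out = input_length, []
    for _ in channels:
        if L < kernel:
            return None
        L = L - kernel + 1
        out.append(L)
        if L < pool:
            return None
        L = L // pool
        out.append(L)
    return out, L * channels[-1]


class TestLayerShapes:
    def test_reference_stack_reproduces_published_sizes(self):
        s = pg.compute_layer_shapes(pg.ModelConfig())
        assert s.lengths == (76, 38, 36, 18, 16, 8, 6, 3)
        assert s.flatten_width == 768

    def test_single_block_arithmetic(self):
        cfg = pg.ModelConfig(input_length=8, conv_channels=(4,), n_classes=2)
        s = pg.compute_layer_shapes(cfg)
        assert s.lengths == (6, 3)

    def test_kernel_exceeding_input_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            pg.ModelConfig(input_length=2, conv_channels=(4,), n_classes=2)
        with pytest.raises(ConfigurationError):
            # valid input but a later layer shrinks below the kernel
            pg.compute_layer_shapes(
                pg.ModelConfig(input_length=10, conv_channels=(4, 4, 4), n_classes=2)
            )

    @given(
        st.integers(8, 200),
        st.lists(st.sampled_from([2, 4, 8, 16]), min_size=1, max_size=4),
        st.integers(2, 5),
        st.integers(2, 3),
    )
    def test_matches_brute_force_recurrence(self, n, channels, kernel, pool):
        expected = _brute_force_shapes(n, channels, kernel, pool)
        try:
            cfg = pg.ModelConfig(
                input_length=n, conv_channels=tuple(channels),
                kernel_size=kernel, pool_size=pool, n_classes=2,
            )
            s = pg.compute_layer_shapes(cfg)
        except ConfigurationError:
            assert expected is None
            return
        assert expected is not None
        assert list(s.lengths) == expected[0]
        assert s.flatten_width == expected[1]


class TestBuildAndPredict:
    def test_dense_input_width_matches_flatten(self):
        m = pg.build_model(pg.ModelConfig())
        assert m.params["dense0_W"].shape == (768, 512)
        assert m.params["dense1_W"].shape == (512, 10)

    def test_same_seed_identical_initial_parameters(self):
        a = pg.build_model(pg.ModelConfig(seed=9))
        b = pg.build_model(pg.ModelConfig(seed=9))
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])
        c = pg.build_model(pg.ModelConfig(seed=10))
        assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)

    def test_untrained_model_refuses_to_predict(self):
        m = pg.build_model(pg.ModelConfig())
        with pytest.raises(StateError):
            pg.predict_frame(m, np.zeros(78))

    def test_softmax_output_normalized_and_order_preserved(self, small_model):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(7, 78))
        probs = pg.predict_batch(small_model, X)
        assert probs.shape == (7, 10)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        # purity: identical input -> identical output; order preserved
        again = pg.predict_batch(small_model, X)
        assert np.array_equal(probs, again)
        one = pg.predict_frame(small_model, X[3])
        assert np.allclose(one.probs, probs[3], atol=1e-7)

    def test_wrong_vector_length_rejected(self, small_model):
        with pytest.raises(ConfigurationError, match="77"):
            pg.predict_batch(small_model, np.zeros((1, 77)))


def _toy_features(n_per_class=50, seed=0):
    """Two linearly separable classes differing in their angle block."""
    rng = np.random.default_rng(seed)
    out = []
    for cls in (0, 1):
        base = np.full(78, 0.5)
        base[66:] = 30.0 if cls == 0 else 150.0
        for _ in range(n_per_class):
            out.append((base + rng.normal(0, 0.5, 78), cls))
    return out


class TestTraining:
    def test_separable_toy_reaches_high_training_accuracy(self):
        cfg = pg.ModelConfig(n_classes=2, epochs=20, seed=3)
        model = pg.train(pg.build_model(cfg), _toy_features(), seed=3)
        log = model.training_log
        assert len(log) == 20
        assert log[-1]["accuracy"] >= 0.95

    def test_training_is_seed_reproducible(self):
        cfg = pg.ModelConfig(n_classes=2, epochs=2, seed=4)
        a = pg.train(pg.build_model(cfg), _toy_features(), seed=4)
        b = pg.train(pg.build_model(cfg), _toy_features(), seed=4)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_wrong_feature_length_is_error(self):
        cfg = pg.ModelConfig(n_classes=2, epochs=1)
        bad = [(np.zeros(77), 0), (np.zeros(77), 1)]
        with pytest.raises(ConfigurationError, match="77"):
            pg.train(pg.build_model(cfg), bad)

    def test_single_class_and_missing_class_rejected(self):
        cfg = pg.ModelConfig(n_classes=2, epochs=1)
        single = [(np.zeros(78), 0) for _ in range(4)]
        with pytest.raises(ConfigurationError, match="missing"):
            pg.train(pg.build_model(cfg), single)
        ten = pg.ModelConfig(epochs=1)
        two_of_ten = [(np.zeros(78), c) for c in (0, 1) for _ in range(3)]
        with pytest.raises(ConfigurationError, match="bird_dog"):
            pg.train(pg.build_model(ten), two_of_ten)

    def test_validation_split_logged(self):
        cfg = pg.ModelConfig(n_classes=2, epochs=2, seed=6)
        model = pg.train(
            pg.build_model(cfg),
            _toy_features(seed=1),
            validation_features=_toy_features(n_per_class=10, seed=2),
            seed=6,
        )
        assert all("val_accuracy" in rec for rec in model.training_log)

    def test_dropout_changes_training_but_keeps_inference_deterministic(self):
        cfg = pg.ModelConfig(n_classes=2, epochs=2, seed=7, dropout_rate=0.5)
        model = pg.train(pg.build_model(cfg), _toy_features(), seed=7)
        X = np.zeros((1, 78))
        assert np.array_equal(
            pg.predict_batch(model, X), pg.predict_batch(model, X)
        )


class TestGradients:
    def test_backprop_matches_numeric_gradients(self):
        """Central-difference check of every parameter group on a tiny
        double-precision network."""
        cfg = pg.ModelConfig(
            input_length=20, n_classes=3, conv_channels=(4, 6),
            dense_units=8, seed=1,
        )
        m = pg.build_model(cfg)
        for k in m.params:
            m.params[k] = m.params[k].astype(np.float64)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 20))
        y = rng.integers(0, 3, size=5)
        eye = np.eye(3)

        def loss():
            p, _ = _forward(m.params, cfg, X)
            return float(
                -np.log(np.clip(p[np.arange(5), y], 1e-12, None)).mean()
            )

        probs, cache = _forward(m.params, cfg, X)
        grads = _backward(m.params, cfg, probs, eye[y], cache)
        eps = 1e-6
        for k, g in grads.items():
            flat_g, flat_p = g.ravel(), m.params[k].ravel()
            for i in rng.choice(flat_p.size, size=min(6, flat_p.size), replace=False):
                old = flat_p[i]
                flat_p[i] = old + eps
                lp = loss()
                flat_p[i] = old - eps
                lm = loss()
                flat_p[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - flat_g[i]) <= 1e-4 * max(1.0, abs(num)), k


class TestCheckpoint:
    def test_round_trip_identical_predictions(self, tmp_path, small_model):
        pg.save_model(small_model, tmp_path / "ckpt")
        loaded = pg.load_model(tmp_path / "ckpt")
        X = np.random.default_rng(5).normal(size=(4, 78))
        assert np.array_equal(
            pg.predict_batch(small_model, X), pg.predict_batch(loaded, X)
        )
        assert loaded.class_names == small_model.class_names
        assert loaded.training_log == small_model.training_log

    def test_truncated_weights_is_integrity_error(self, tmp_path, small_model):
        path = pg.save_model(small_model, tmp_path / "ckpt")
        data = (path / "weights.npz").read_bytes()
        (path / "weights.npz").write_bytes(data[: len(data) // 2])
        with pytest.raises(IntegrityError):
            pg.load_model(path)

    def test_registry_size_mismatch_is_integrity_error(self, tmp_path, small_model):
        import json

        path = pg.save_model(small_model, tmp_path / "ckpt")
        meta = json.loads((path / "config.json").read_text())
        meta["class_names"] = meta["class_names"][:-1]
        (path / "config.json").write_text(json.dumps(meta))
        with pytest.raises(IntegrityError):
            pg.load_model(path)

    def test_weight_shape_mismatch_is_integrity_error(self, tmp_path, small_model):
        import json

        path = pg.save_model(small_model, tmp_path / "ckpt")
        meta = json.loads((path / "config.json").read_text())
        meta["config"]["dense_units"] = 64
        (path / "config.json").write_text(json.dumps(meta))
        with pytest.raises(IntegrityError):
            pg.load_model(path)
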