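"""Surrogate CNN: forward contract, gradients, training loop, freezing."""

import numpy as np
import pytest

from wsicascade import (
    EGFR_CLASSES,
    REFERENCE_CONFIGS,
    TUMOR_CLASSES,
    SmallConvNet,
    TrainingConfig,
    ValidationError,
    train_classifier,
)
from wsicascade.backbone import _tiles_to_array, bce_loss

from conftest import make_tile


def tiny_net(seed=0, channels=(4, 6)):
    # 46 = 2 * 23: same working resolution as the full-size tile
    return SmallConvNet(TUMOR_CLASSES, channels=channels, input_size=46, pool=2, seed=seed)


def two_color_set(n_per_class, size=46, seed=0):
    rng = np.random.default_rng(seed)
    tiles = []
    for i in range(n_per_class):
        tiles.append((make_tile((225, 195, 215), size=size, noise_rng=rng, noise_sd=8), TUMOR_CLASSES[0]))
        tiles.append((make_tile((150, 100, 170), size=size, noise_rng=rng, noise_sd=8), TUMOR_CLASSES[1]))
    return tiles


class TestForwardContract:
    def test_probabilities_normalized_and_deterministic(self, rng):
        net = tiny_net()
        x = rng.integers(0, 255, (5, 46, 46, 3), dtype=np.uint8).astype(np.uint8)
        p = net.predict_proba(x)
        assert p.shape == (5, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(p, net.predict_proba(x))
        # duplicated tile gives an identical pair
        np.testing.assert_array_equal(p[0], net.predict_proba(x[[0, 0]])[1])

    def test_empty_batch_and_bad_shape(self):
        net = tiny_net()
        assert net.predict_proba([]).shape == (0, 2)
        with pytest.raises(ValidationError):
            net.predict_proba(np.zeros((1, 30, 30, 3), np.uint8))

    def test_save_load_roundtrip(self, tmp_path, rng):
        net = tiny_net(seed=3)
        x = rng.integers(0, 255, (3, 46, 46, 3), dtype=np.uint8).astype(np.uint8)
        net.save(tmp_path / "m.npz")
        loaded = SmallConvNet.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(net.predict_proba(x), loaded.predict_proba(x))
        assert loaded.class_names == net.class_names


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic parameter gradients agree with central differences."""
        net = SmallConvNet(TUMOR_CLASSES, channels=(3,), input_size=8, pool=2, seed=1)
        rng = np.random.default_rng(0)
        x = rng.random((2, 4, 4, 3))
        y = np.array([0, 1])

        def loss_now():
            return bce_loss(net._forward(x, pooled=True)["probs"], y)

        cache = net._forward(x, pooled=True)
        onehot = np.zeros((2, 2))
        onehot[np.arange(2), y] = 1.0
        dlogits = (cache["probs"] - onehot) / 2
        grads, _ = net._backward(cache, dlogits)

        eps = 1e-6
        for grp, grd in zip(net.parameter_groups(), grads):
            w = grp["W"]
            for idx in [(0, 0), (w.shape[0] - 1, w.shape[1] - 1)]:
                orig = w[idx]
                w[idx] = orig + eps
                up = loss_now()
                w[idx] = orig - eps
                down = loss_now()
                w[idx] = orig
                num = (up - down) / (2 * eps)
                assert abs(num - grd["W"][idx]) < 1e-6

    def test_activation_gradient_layer_names(self):
        net = tiny_net()
        t = make_tile(size=46)
        act, grad = net.activation_and_gradient(t, "relu_2", 1)
        assert act.shape == grad.shape == (23, 23, 6)
        with pytest.raises(ValidationError):
            net.activation_and_gradient(t, "relu_9", 1)


class TestTraining:
    def test_separable_classes_reach_high_accuracy(self):
        """Two well-separated color textures are learned within 10 epochs."""
        data = two_color_set(100)
        val = two_color_set(30, seed=99)
        cfg = TrainingConfig(learning_rate=0.05, batch_size=32, max_epochs=10, rng_seed=0)
        model, hist = train_classifier(
            data, val, cfg, builder=lambda names, seed: tiny_net(seed), class_names=TUMOR_CLASSES
        )
        assert hist[-1]["val_accuracy"] >= 0.95

    def test_single_class_rejected(self):
        data = [(make_tile(size=46), TUMOR_CLASSES[0])] * 4
        with pytest.raises(ValidationError):
            train_classifier(data, [], TrainingConfig(), builder=lambda n, s: tiny_net(s))

    def test_full_freeze_only_updates_head(self):
        data = two_color_set(20)
        cfg = TrainingConfig(learning_rate=0.05, batch_size=16, max_epochs=3, frozen_layers=2, rng_seed=0)
        model, _ = train_classifier(data, [], cfg, builder=lambda n, s: tiny_net(s))
        fresh = tiny_net(cfg.rng_seed)
        for w0, w1 in zip(fresh.conv_w, model.conv_w):
            np.testing.assert_array_equal(w0, w1)
        assert not np.array_equal(fresh.head_w, model.head_w)

    def test_freeze_depth_validated(self):
        data = two_color_set(4)
        cfg = TrainingConfig(frozen_layers=3)
        with pytest.raises(ValidationError):
            train_classifier(data, [], cfg, builder=lambda n, s: tiny_net(s))

    def test_freezing_monotonicity(self):
        """More frozen layers -> strictly fewer updated parameter groups."""
        data = two_color_set(20)
        updated_counts = []
        for k in (0, 1, 2):
            cfg = TrainingConfig(learning_rate=0.05, batch_size=16, max_epochs=2, frozen_layers=k, rng_seed=0)
            model, _ = train_classifier(data, [], cfg, builder=lambda n, s: tiny_net(s))
            fresh = tiny_net(0)
            changed = sum(
                not np.array_equal(a["W"], b["W"])
                for a, b in zip(fresh.parameter_groups(), model.parameter_groups())
            )
            updated_counts.append(changed)
        assert updated_counts[0] > updated_counts[1] > updated_counts[2] >= 1

    def test_same_seed_same_loss_curve(self):
        data = two_color_set(20)
        val = two_color_set(6, seed=5)
        cfg = TrainingConfig(learning_rate=0.05, batch_size=16, max_epochs=4, rng_seed=11)
        _, h1 = train_classifier(data, val, cfg, builder=lambda n, s: tiny_net(s))
        _, h2 = train_classifier(data, val, cfg, builder=lambda n, s: tiny_net(s))
        assert h1 == h2  # bitwise-identical losses

    def test_reported_val_loss_matches_predict_proba(self):
        """The loop's validation loss equals BCE recomputed from the contract."""
        data = two_color_set(20)
        val = two_color_set(8, seed=5)
        cfg = TrainingConfig(learning_rate=0.05, batch_size=16, max_epochs=1, patience=99, rng_seed=2)
        model, hist = train_classifier(data, val, cfg, builder=lambda n, s: tiny_net(s))
        probs = model.predict_proba([t for t, _ in val])
        y = np.array([0 if lab == TUMOR_CLASSES[0] else 1 for _, lab in val])
        assert abs(hist[-1]["val_loss"] - bce_loss(probs, y)) < 1e-6

    def test_pooled_fast_path_equals_contract_path(self, rng):
        net = tiny_net(4)
        x = rng.integers(0, 255, (3, 46, 46, 3), dtype=np.uint8).astype(np.uint8)
        xf = _tiles_to_array(x)
        np.testing.assert_allclose(
            net._forward(xf)["probs"],
            net._forward(net._downsample(xf), pooled=True)["probs"],
            atol=1e-12,
        )


def test_reference_configs_record_published_hyperparameters():
    t, e = REFERENCE_CONFIGS["tumor"], REFERENCE_CONFIGS["egfr"]
    assert (t.frozen_layers, t.learning_rate, t.batch_size, t.momentum) == (471, 0.001, 128, 0.9)
    assert (e.frozen_layers, e.learning_rate, e.batch_size, e.momentum) == (1, 0.001, 64, 0.9)
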