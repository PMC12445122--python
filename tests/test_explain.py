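"""Grad-CAM correctness, HD-CAM fusion, and explanation-tile selection."""

import warnings

import numpy as np
import pytest

from wsicascade import (
    EGFR_CLASSES,
    TUMOR_CLASSES,
    SmallConvNet,
    TileRecord,
    TrainingConfig,
    ValidationError,
    grad_cam,
    hd_cam,
    linear_fusion_weights,
    select_top_confident_correct,
    train_classifier,
)
from wsicascade.cascade import TileVote
from wsicascade.explain import _minmax

from conftest import make_tile


class TestFusionWeights:
    def test_linear_scheme(self):
        w = linear_fusion_weights(10)
        assert w[-1] / w[0] == pytest.approx(10.0)
        assert w.sum() == pytest.approx(1.0)
        assert (np.diff(w) > 0).all()

    def test_single_layer(self):
        assert linear_fusion_weights(1) == pytest.approx([1.0])

    def test_scale_invariance_of_normalized_fusion(self, rng):
        """Doubling all weights leaves the min-max-normalized map unchanged."""
        maps = [rng.random((8, 8)) for _ in range(3)]
        w = linear_fusion_weights(3)
        combined = sum(wi * m for wi, m in zip(w, maps))
        doubled = sum(2 * wi * m for wi, m in zip(w, maps))
        np.testing.assert_allclose(_minmax(combined)[0], _minmax(doubled)[0], atol=1e-12)

    def test_identical_maps_fuse_to_themselves(self, rng):
        m = rng.random((8, 8))
        w = linear_fusion_weights(10)
        fused = sum(wi * m for wi in w)
        np.testing.assert_allclose(fused, m, atol=1e-12)


class TestGradCam:
    def _single_channel_net(self):
        """1-conv net whose class-1 logit depends on channel 0 alone."""
        net = SmallConvNet(EGFR_CLASSES, channels=(2,), input_size=4, pool=2, seed=0)
        net.head_w = np.array([[0.0, 1.0], [0.0, 0.0]])  # class 1 <- channel 0 only
        net.head_b = np.zeros(2)
        return net

    def test_hand_computed_single_channel_map(self, rng):
        """On a 2x2 activation the map equals that channel's normalized
        activation: alpha = (1/HW, 0), map = relu(a0/HW) -> minmax(a0)."""
        net = self._single_channel_net()
        t = TileRecord("s", 0, 0, 0, 0, rng.integers(0, 255, (4, 4, 3), dtype=np.uint8).astype(np.uint8))
        act, grad = net.activation_and_gradient(t, "relu_1", 1)
        assert act.shape == (2, 2, 2)
        np.testing.assert_allclose(grad[..., 0], 0.25, atol=1e-12)  # 1/(2*2)
        np.testing.assert_allclose(grad[..., 1], 0.0, atol=1e-12)
        cam = grad_cam(net, t, "relu_1", 1, tile_size=4)
        expected, _ = _minmax(np.maximum(act[..., 0] * 0.25, 0.0))
        np.testing.assert_allclose(cam.native, expected, atol=1e-12)

    def test_zero_gradient_gives_flagged_zero_map(self, rng):
        net = self._single_channel_net()
        t = TileRecord("s", 0, 0, 0, 0, rng.integers(0, 255, (4, 4, 3), dtype=np.uint8).astype(np.uint8))
        with pytest.warns(UserWarning, match="all-zero"):
            cam = grad_cam(net, t, "relu_1", 0)  # class 0 has zero head weights
        assert cam.all_zero and cam.native.max() == 0.0

    def test_maps_bounded_in_unit_interval(self, rng):
        net = SmallConvNet(TUMOR_CLASSES, channels=(4, 4), input_size=8, pool=2, seed=2)
        for _ in range(5):
            t = TileRecord("s", 0, 0, 0, 0, rng.integers(0, 255, (8, 8, 3), dtype=np.uint8).astype(np.uint8))
            cam = grad_cam(net, t, "relu_2", 1, tile_size=8)
            assert 0.0 <= cam.native.min() and cam.native.max() <= 1.0
            assert cam.upsampled.shape == (8, 8)

    def test_unknown_layer_rejected(self):
        net = self._single_channel_net()
        with pytest.raises(ValidationError):
            grad_cam(net, make_tile(size=4), "dense", 0)


class TestHdCam:
    def test_single_layer_fusion_equals_grad_cam(self, rng):
        net = SmallConvNet(EGFR_CLASSES, channels=(3,), input_size=8, pool=2, seed=1)
        t = TileRecord("s", 0, 0, 0, 0, rng.integers(0, 255, (8, 8, 3), dtype=np.uint8).astype(np.uint8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = hd_cam(net, t, target_class=1, n_layers=1, tile_size=8)
            cam = grad_cam(net, t, "relu_1", 1, tile_size=8)
        np.testing.assert_allclose(res.combined, _minmax(cam.upsampled)[0], atol=1e-12)
        assert res.fusion_weights == (1.0,)

    def test_ten_layer_depth_weighting(self, rng):
        net = SmallConvNet(EGFR_CLASSES, channels=(2,) * 10, input_size=8, pool=2, seed=3)
        t = TileRecord("s", 0, 0, 0, 0, rng.integers(0, 255, (8, 8, 3), dtype=np.uint8).astype(np.uint8))
        res = hd_cam(net, t, n_layers=10, tile_size=8)
        assert len(res.layer_maps) == 10
        assert res.fusion_weights[-1] / res.fusion_weights[0] == pytest.approx(10.0)
        assert [m.layer for m in res.layer_maps] == [f"relu_{i}" for i in range(1, 11)]
        assert 0.0 <= res.combined.min() and res.combined.max() <= 1.0

    def test_fewer_layers_than_requested_warns_and_uses_all(self, rng):
        net = SmallConvNet(EGFR_CLASSES, channels=(2, 2), input_size=8, pool=2, seed=3)
        t = TileRecord("s", 0, 0, 0, 0, rng.integers(0, 255, (8, 8, 3), dtype=np.uint8).astype(np.uint8))
        with pytest.warns(UserWarning, match="using all"):
            res = hd_cam(net, t, n_layers=10, tile_size=8)
        assert len(res.layer_maps) == 2

    def test_localizes_planted_discriminative_region(self):
        """The fused map concentrates on the half of the tile that carries
        the class-discriminative color (>=90% of tiles)."""

        def half_tile(left, rng, row=0, col=0):
            px = np.empty((46, 46, 3))
            px[:, :23] = left
            px[:, 23:] = (180, 160, 190)  # shared neutral half
            px += rng.normal(0, 6, px.shape)
            return TileRecord("s", row, col, 0, 0, np.clip(px, 0, 255).astype(np.uint8))

        rng = np.random.default_rng(0)
        train = [(half_tile((170, 150, 180), rng), "WT") for _ in range(60)]
        train += [(half_tile((110, 90, 190), rng), "EGFR") for _ in range(60)]
        val = [(half_tile((170, 150, 180), rng), "WT") for _ in range(10)]
        val += [(half_tile((110, 90, 190), rng), "EGFR") for _ in range(10)]
        cfg = TrainingConfig(learning_rate=0.05, batch_size=32, max_epochs=15, rng_seed=0)
        builder = lambda n, s: SmallConvNet(n, channels=(8, 8), input_size=46, pool=2, seed=s)
        model, hist = train_classifier(train, val, cfg, builder=builder, class_names=EGFR_CLASSES)
        assert hist[-1]["val_accuracy"] >= 0.95

        hits = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for _ in range(20):
                t = half_tile((110, 90, 190), rng)
                m = hd_cam(model, t, target_class="EGFR", n_layers=10, tile_size=46).combined
                hits += m[:, :23].mean() > m[:, 23:].mean()
        assert hits >= 18  # >= 90% of tiles


class TestSelection:
    def _vote(self, conf, decision, row, col):
        p = (1 - conf, conf) if decision == "EGFR" else (conf, 1 - conf)
        return TileVote("s", row, col, "egfr", EGFR_CLASSES, p, conf, decision, conf <= 0.9)

    def test_top_k_per_class_by_confidence(self):
        votes = [
            (self._vote(0.99, "EGFR", 0, 0), "EGFR"),
            (self._vote(0.97, "EGFR", 0, 1), "EGFR"),
            (self._vote(0.92, "EGFR", 0, 2), "EGFR"),
            (self._vote(0.98, "WT", 1, 0), "WT"),
        ]
        got = select_top_confident_correct(votes, k=2)
        assert [(v.confidence, v.decision) for v in got] == [(0.99, "EGFR"), (0.97, "EGFR"), (0.98, "WT")]

    def test_misclassified_tiles_excluded(self):
        votes = [(self._vote(0.99, "EGFR", 0, 0), "WT"), (self._vote(0.95, "WT", 0, 1), "EGFR")]
        with pytest.warns(UserWarning):
            assert select_top_confident_correct(votes, k=1) == []

    def test_tie_broken_by_grid_position(self):
        votes = [
            (self._vote(0.95, "EGFR", 2, 0), "EGFR"),
            (self._vote(0.95, "EGFR", 0, 5), "EGFR"),
            (self._vote(0.95, "EGFR", 0, 3), "EGFR"),
        ]
        got = select_top_confident_correct(votes, k=2)
        assert [(v.grid_row, v.grid_col) for v in got] == [(0, 3), (0, 5)]
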