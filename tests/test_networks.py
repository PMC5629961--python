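"""Architecture contracts, gradients, training behavior, map prediction."""

import numpy as np
import pytest

from glandseg import _nn
from glandseg.networks import (
    Network,
    TrainConfig,
    build_network,
    predict_maps,
    spatial_size_chain,
    train_network,
)
from glandseg.preprocess import StructureChannel

from _fixtures import separable_patches, small_spec, tiny_spec


def reference_size_chain(spec):
    """Independent per-layer size recurrence: valid conv, floor 2x2 pool."""
    sizes = [spec.patch_size]
    for layer in spec.layers:
        if layer.kind == "conv":
            sizes.append(sizes[-1] - (layer.kernel - 1))
        elif layer.kind == "pool":
            sizes.append(sizes[-1] // 2)
    return sizes


class TestArchitecture:
    def test_object_variant_contract(self):
        spec = build_network("object")
        assert spec.output_units == 4
        assert spec.weighted_layers == 7
        assert spec.n_conv == 4 and spec.n_fc == 3
        convs = [l for l in spec.layers if l.kind == "conv"]
        assert [(c.units, c.kernel) for c in convs] == [
            (80, 11), (96, 7), (128, 5), (160, 3)
        ]

    def test_separator_variant_contract(self):
        spec = build_network("separator")
        assert spec.output_units == 2
        convs = [l for l in spec.layers if l.kind == "conv"]
        assert [(c.units, c.kernel) for c in convs] == [
            (64, 9), (96, 7), (128, 5), (160, 3)
        ]
        fcs = [l.units for l in spec.layers if l.kind == "fc"]
        assert fcs == [1024, 512, 2]

    def test_object_spatial_size_chain(self):
        spec = build_network("object")
        assert spatial_size_chain(spec) == [101, 91, 45, 39, 19, 15, 7, 5]
        assert spatial_size_chain(spec) == reference_size_chain(spec)

    def test_pooling_follows_first_three_convs_only(self):
        for variant in ("object", "separator"):
            kinds = [l.kind for l in build_network(variant).layers]
            assert kinds.count("pool") == 3
            # a pool directly follows each of conv 1..3, none after conv 4
            conv_positions = [i for i, k in enumerate(kinds) if k == "conv"]
            for pos in conv_positions[:3]:
                assert kinds[pos + 1] == "pool"
            assert kinds[conv_positions[3] + 1] == "fc"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_network("wrong")

    def test_parameter_count_deterministic(self):
        a = Network(build_network("object"), seed=5)
        b = Network(build_network("object"), seed=5)
        assert a.n_parameters() == b.n_parameters()
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa, pb)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, rng):
        net = Network(tiny_spec(3), seed=0, dropout=0.0)
        x = rng.random((4, 9, 9)).astype(np.float32)
        y = np.array([0, 1, 2, 0])
        logits = net.forward(x, train=True, rng=rng)
        _, d = _nn.softmax_cross_entropy(logits, y)
        net.backward(d)
        grads = [g.copy() for g in net.grads]

        def loss():
            return _nn.softmax_cross_entropy(net.forward(x), y)[0]

        rel_errors = []
        sampler = np.random.default_rng(2)
        for pi, p in enumerate(net.params):
            for _ in range(8):
                idx = tuple(sampler.integers(0, s) for s in p.shape)
                orig = float(p[idx])
                eps = 1e-2
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                rel_errors.append(abs(num - grads[pi][idx]) / max(abs(num), 1e-3))
        # ReLU kinks make a few samples unreliable; the bulk must agree
        assert np.median(rel_errors) < 1e-3


class TestTraining:
    def test_separable_patches_reach_low_error(self):
        res = train_network(
            tiny_spec(2, patch_size=9),
            separable_patches(30, 2, 9, seed=0),
            separable_patches(15, 2, 9, seed=1),
            TrainConfig(seed=0, batch_size=4, max_epochs=50),
        )
        assert res.best_valid_error < 0.05
        assert {"epoch", "train_error", "valid_error", "loss"} <= set(res.history.columns)

    def test_epoch_one_loss_reproducible(self):
        kwargs = dict(
            spec=tiny_spec(2, patch_size=9),
            train=separable_patches(10, 2, 9, seed=0),
            valid=separable_patches(5, 2, 9, seed=1),
        )
        cfg = TrainConfig(seed=3, batch_size=5, max_epochs=1)
        a = train_network(config=cfg, **kwargs)
        b = train_network(config=cfg, **kwargs)
        assert a.history.loss.iloc[0] == b.history.loss.iloc[0]

    def test_patience_stops_training(self, rng):
        # random labels: validation cannot improve systematically
        train = separable_patches(10, 2, 9, seed=0)
        train.labels = rng.integers(0, 2, len(train))
        valid = separable_patches(10, 2, 9, seed=1)
        valid.labels = rng.integers(0, 2, len(valid))
        cfg = TrainConfig(seed=0, batch_size=5, max_epochs=200, patience_epochs=3)
        res = train_network(tiny_spec(2, patch_size=9), train, valid, cfg)
        if res.stop_reason == "patience":
            assert len(res.history) <= res.best_epoch + cfg.patience_epochs + 1

    def test_class_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            train_network(
                tiny_spec(4, patch_size=9),
                separable_patches(5, 2, 9, seed=0),
                separable_patches(5, 2, 9, seed=1),
                TrainConfig(seed=0, max_epochs=1),
            )

    def test_schedule_shapes(self):
        cfg = TrainConfig()
        assert cfg.eta0 == 0.0025
        assert cfg.learning_rate(0) == pytest.approx(0.0025)
        assert cfg.learning_rate(100) == pytest.approx(0.0005)
        assert cfg.learning_rate(150) == pytest.approx(0.0005)
        assert cfg.momentum(0) == pytest.approx(0.8)
        assert cfg.momentum(50) == pytest.approx(0.99)
        assert cfg.momentum(80) == pytest.approx(0.99)
        assert cfg.patience_epochs == 20 and cfg.batch_size == 200


@pytest.fixture(scope="module")
def trained_tiny():
    res = train_network(
        tiny_spec(4, patch_size=9),
        separable_patches(20, 4, 9, seed=0),
        separable_patches(10, 4, 9, seed=1),
        TrainConfig(seed=0, batch_size=4, max_epochs=30),
    )
    return res.network


class TestPrediction:
    def test_sliding_window_equals_per_patch_forward(self, trained_tiny, rng):
        """Stride-1 map prediction is the per-pixel window classification."""
        channel = StructureChannel(rng.uniform(0, 255, (10, 10)))
        maps = predict_maps(trained_tiny, channel, stride=1)
        half = trained_tiny.spec.patch_size // 2
        padded = np.pad(channel.pixels / 255.0, half, mode="reflect")
        for r, c in [(0, 0), (3, 7), (9, 9), (5, 5)]:
            patch = padded[r:r + 9, c:c + 9][None].astype(np.float32)
            expected = _nn.softmax(trained_tiny.forward(patch))[0]
            assert np.allclose(maps.maps[:, r, c], expected, atol=1e-6)

    def test_probabilities_normalized_and_shaped(self, trained_tiny, rng):
        channel = StructureChannel(rng.uniform(0, 255, (12, 8)))
        maps = predict_maps(trained_tiny, channel)
        assert maps.shape == (12, 8)
        assert np.allclose(maps.maps.sum(axis=0), 1.0, atol=1e-5)

    def test_constant_input_gives_constant_maps(self, trained_tiny):
        channel = StructureChannel(np.full((10, 10), 128.0))
        maps = predict_maps(trained_tiny, channel)
        for m in maps.maps:
            assert np.ptp(m) < 1e-6  # mirror padding keeps borders constant too

    def test_strided_prediction_full_size_and_normalized(self, trained_tiny, rng):
        channel = StructureChannel(rng.uniform(0, 255, (11, 13)))
        maps = predict_maps(trained_tiny, channel, stride=2)
        assert maps.shape == (11, 13)
        assert np.allclose(maps.maps.sum(axis=0), 1.0, atol=1e-9)

    def test_untrained_network_rejected(self, rng):
        net = Network(tiny_spec(4, patch_size=9), seed=0)
        with pytest.raises(RuntimeError, match="trained"):
            predict_maps(net, StructureChannel(np.zeros((5, 5))))

    def test_checkpoint_roundtrip(self, trained_tiny, tmp_path, rng):
        path = tmp_path / "net.npz"
        trained_tiny.save(path)
        back = Network.load(path)
        x = rng.random((3, 9, 9)).astype(np.float32)
        assert np.allclose(back.predict_proba(x), trained_tiny.predict_proba(x))
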